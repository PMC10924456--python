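"""Map-level readouts of a trained BLSOM.

Four views explain a trained lattice:

* territory map — each node colored by the single category (species,
  lineage group, or chromosome) of its occupants, black when occupants mix
  categories, blank when vacant;
* U-matrix — mean Euclidean distance between a node's weight and its
  existing 8-neighbors' weights, min-max normalized; high values trace
  cluster boundaries;
* per-oligonucleotide heatmap — each node's weight-vector frequency for one
  class, binned into 21 equal divisions between the map-wide minimum and
  maximum;
* special-zone candidates — satellite single-category components separated
  from the category's main territory by high-U boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .blsom import BLSOMModel

VACANT = "vacant"
MULTIPLE = "multiple"

_EIGHT = np.ones((3, 3), dtype=int)


def _require_assignments(model: BLSOMModel) -> np.ndarray:
    if model.assignments is None:
        raise ValueError("model carries no fragment assignments; train or assign first")
    return model.assignments


def territory_map(model: BLSOMModel, labels) -> np.ndarray:
    """Per-node category grid of dtype object, shape (I, J).

    Values are ``"single:<label>"`` for nodes whose occupants share one
    label, ``"multiple"`` for mixed nodes (rendered black), ``"vacant"`` for
    unoccupied nodes (rendered blank).
    """
    assignments = _require_assignments(model)
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != assignments.shape[0]:
        raise ValueError("one label per assigned fragment is required")
    if any(lab is None or (isinstance(lab, float) and np.isnan(lab)) for lab in labels):
        raise ValueError("unlabeled fragment encountered")
    grid = np.full((model.I, model.J), VACANT, dtype=object)
    node_labels: dict[tuple[int, int], set] = {}
    for (i, j), lab in zip(assignments, labels):
        node_labels.setdefault((int(i), int(j)), set()).add(lab)
    for (i, j), labs in node_labels.items():
        grid[i, j] = f"single:{next(iter(labs))}" if len(labs) == 1 else MULTIPLE
    return grid


def compute_umatrix(model: BLSOMModel) -> np.ndarray:
    """Per-node mean distance to existing 8-neighbors, normalized to [0, 1]."""
    I, J = model.I, model.J
    if I * J <= 1:
        raise ValueError("U-matrix undefined on a 1x1 lattice")
    w = model.weights
    u = np.zeros((I, J))
    counts = np.zeros((I, J))
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            src_i = slice(max(0, -di), I - max(0, di))
            src_j = slice(max(0, -dj), J - max(0, dj))
            dst_i = slice(max(0, di), I - max(0, -di))
            dst_j = slice(max(0, dj), J - max(0, -dj))
            diff = w[dst_i, dst_j] - w[src_i, src_j]
            dist = np.sqrt((diff * diff).sum(axis=-1))
            u[dst_i, dst_j] += dist
            counts[dst_i, dst_j] += 1
    u /= counts
    lo, hi = u.min(), u.max()
    if hi == lo:
        return np.zeros((I, J))
    return (u - lo) / (hi - lo)


def heatmap_bins(model: BLSOMModel, index, class_label: str) -> np.ndarray:
    """21-division bin (0..20) of one oligonucleotide's node-weight frequency.

    bin = floor(21 * (f - fmin) / (fmax - fmin)) clamped to 0..20; a node at
    the map-wide maximum gets 20 (dark red), the minimum gets 0 (dark blue).
    If the frequency is constant across the map every node gets the neutral
    middle bin 10.
    """
    col = index.class_index(class_label)
    f = model.weights[:, :, col]
    fmin, fmax = f.min(), f.max()
    if fmax == fmin:
        return np.full((model.I, model.J), 10, dtype=np.int64)
    bins = np.floor(21.0 * (f - fmin) / (fmax - fmin)).astype(np.int64)
    return np.clip(bins, 0, 20)


def map_purity(model: BLSOMModel, labels) -> float:
    """Fraction of fragments sitting on single-category nodes."""
    assignments = _require_assignments(model)
    grid = territory_map(model, labels)
    cats = grid[assignments[:, 0], assignments[:, 1]]
    return float(np.mean([str(c).startswith("single:") for c in cats]))


@dataclass
class SpecialZone:
    """A satellite single-category component bounded by high-U nodes."""

    label: str
    nodes: list[tuple[int, int]]
    boundary_u_mean: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def flag_special_zone_candidates(
    model: BLSOMModel,
    labels,
    umatrix: np.ndarray | None = None,
    quantile: float = 0.9,
) -> list[SpecialZone]:
    """Flag satellite territories ("special zones").

    For each category, the 8-connected components of its single-category
    nodes are found; the largest component is the main territory.  Any other
    component is flagged when the nodes surrounding it (the 8-adjacent ring
    just outside the component, where the U-matrix draws its boundary
    "black line") have a mean U-matrix value at or above the given quantile
    of all U values.
    """
    if umatrix is None:
        umatrix = compute_umatrix(model)
    grid = territory_map(model, labels)
    threshold = float(np.quantile(umatrix, quantile))
    zones: list[SpecialZone] = []
    cat_labels = sorted(
        {str(c)[len("single:"):] for c in grid.ravel() if str(c).startswith("single:")}
    )
    for lab in cat_labels:
        mask = grid == f"single:{lab}"
        comp, n_comp = ndimage.label(mask, structure=_EIGHT)
        if n_comp <= 1:
            continue
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n_comp + 1))
        main = int(np.argmax(sizes)) + 1
        for c in range(1, n_comp + 1):
            if c == main:
                continue
            cmask = comp == c
            ring = ndimage.binary_dilation(cmask, structure=_EIGHT) & ~cmask
            if not ring.any():  # component covers the whole lattice side
                ring = cmask
            u_mean = float(umatrix[ring].mean())
            if u_mean >= threshold:
                nodes = [tuple(map(int, ij)) for ij in np.argwhere(cmask)]
                zones.append(SpecialZone(label=lab, nodes=nodes, boundary_u_mean=u_mean))
    return zones


def node_table(model: BLSOMModel, labels, umatrix: np.ndarray | None = None) -> pd.DataFrame:
    """Long-format per-node table: i, j, category, umatrix, n_fragments."""
    if umatrix is None:
        umatrix = compute_umatrix(model)
    grid = territory_map(model, labels)
    occupancy = model.node_occupancy()
    rows = []
    for i in range(model.I):
        for j in range(model.J):
            rows.append(
                {
                    "i": i,
                    "j": j,
                    "category": grid[i, j],
                    "umatrix": umatrix[i, j],
                    "n_fragments": int(occupancy[i, j]),
                }
            )
    return pd.DataFrame(rows)


def special_zone_table(
    model: BLSOMModel, matrix, zones: list[SpecialZone]
) -> pd.DataFrame:
    """Fragment-level table of flagged zones: species, zone name, source, start, end."""
    assignments = _require_assignments(model)
    rows = []
    for zi, zone in enumerate(zones):
        node_set = set(zone.nodes)
        name = f"{zone.label}_SZ{zi + 1}"
        for fi, (i, j) in enumerate(assignments):
            if (int(i), int(j)) in node_set:
                frag = matrix.fragments.iloc[fi]
                rows.append(
                    {
                        "species": frag["species"],
                        "zone": name,
                        "source": frag["source"],
                        "start": int(frag["start"]),
                        "end": int(frag["end"]),
                    }
                )
    return pd.DataFrame(rows, columns=["species", "zone", "source", "start", "end"])


# ---------------------------------------------------------------------------
# rendering


def _heatmap_cmap(palette: str):
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    if palette == "red_blue":
        return plt.get_cmap("RdBu_r", 21)
    if palette == "orange_blue":
        return LinearSegmentedColormap.from_list(
            "orange_blue", ["#08306b", "#f7f7f7", "#e65100"], N=21
        )
    raise ValueError(f"unknown palette {palette!r}")


def render_territory(grid: np.ndarray, path, title: str = "") -> None:
    """Render a territory grid: per-category colors, black=multiple, white=vacant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    cats = sorted({str(c) for c in grid.ravel() if str(c).startswith("single:")})
    cmap_base = plt.get_cmap("tab20")
    color_of = {VACANT: (1, 1, 1, 1), MULTIPLE: (0, 0, 0, 1)}
    for i, c in enumerate(cats):
        color_of[c] = cmap_base(i % 20)
    codes = {c: i for i, c in enumerate(color_of)}
    img = np.vectorize(lambda c: codes[str(c)])(grid)
    fig, ax = plt.subplots(figsize=(6, 6 * grid.shape[1] / max(grid.shape[0], 1)))
    ax.imshow(img.T, cmap=ListedColormap(list(color_of.values())), origin="lower",
              vmin=0, vmax=len(color_of) - 1, interpolation="nearest")
    ax.set_xlabel("i (first PC axis)")
    ax.set_ylabel("j (second PC axis)")
    ax.set_title(title)
    handles = [Patch(color=color_of[c], label=c.replace("single:", "")) for c in cats]
    handles.append(Patch(color="black", label="multiple"))
    ax.legend(handles=handles, loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize=7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def render_umatrix(umatrix: np.ndarray, path, title: str = "U-matrix") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6 * umatrix.shape[1] / max(umatrix.shape[0], 1)))
    im = ax.imshow(umatrix.T, cmap="Greys", origin="lower", interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def render_heatmap(
    bins: np.ndarray, path, title: str = "", palette: str = "red_blue"
) -> None:
    """Render 21-bin oligonucleotide contribution levels (dark red = very high)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6 * bins.shape[1] / max(bins.shape[0], 1)))
    im = ax.imshow(
        bins.T, cmap=_heatmap_cmap(palette), origin="lower",
        vmin=0, vmax=20, interpolation="nearest",
    )
    fig.colorbar(im, ax=ax, shrink=0.8, ticks=[0, 10, 20])
    ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
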