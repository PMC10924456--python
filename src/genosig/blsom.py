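"""Batch-learning self-organizing map (BLSOM) for composition vectors.

The conventional Kohonen SOM depends on the order in which data are
presented.  The batch variant removes that dependence: every epoch first
assigns all fragments to their best-matching node (smallest Euclidean
distance), then replaces each node's weight with a neighborhood-weighted
mean of the fragments assigned near it.  Initialization is deterministic
from the principal components of the data rather than random, and the
lattice aspect ratio follows the sigma1/sigma2 ratio of the first two
components, each axis spanning five standard deviations.

To make training bit-identical under any permutation of the input rows, the
matrix is sorted into a canonical row order before PCA and training, and
assignments are mapped back through the inverse permutation afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class BLSOMConfig:
    """Training hyperparameters.

    seqs_per_node : target average number of fragments per lattice node
        (node count ~ N / seqs_per_node).
    sd_multiplier : lattice width in units of the PC standard deviation
        (5 means the axis spans 5 * sigma).
    epochs : number of batch assignment/update rounds (order of a few
        hundred).
    neighborhood_initial_radius / neighborhood_final_radius : truncated
        Gaussian kernel radius, decayed linearly over epochs; None for the
        initial radius means max(I, J) / 2 at training time.
    """

    seqs_per_node: float = 10.0
    sd_multiplier: float = 5.0
    epochs: int = 200
    neighborhood_initial_radius: float | None = None
    neighborhood_final_radius: float = 1.0
    min_J: int = 2
    standardize_columns: bool = False

    def __post_init__(self):
        if self.seqs_per_node <= 0 or self.sd_multiplier <= 0:
            raise ValueError("seqs_per_node and sd_multiplier must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.neighborhood_final_radius < 0:
            raise ValueError("neighborhood_final_radius must be >= 0")
        if self.min_J < 2:
            raise ValueError("min_J must be >= 2")


@dataclass
class BLSOMModel:
    """A (possibly trained) lattice of weight vectors.

    weights has shape (I, J, d) in composition-percentage units; assignments
    maps each fragment row to its (i, j) best-matching node.
    """

    I: int
    J: int
    weights: np.ndarray = field(repr=False)
    sigma1: float
    sigma2: float
    mean: np.ndarray = field(repr=False)
    trained: bool = False
    assignments: np.ndarray | None = field(default=None, repr=False)
    # optional per-column standardization applied to inputs before matching
    col_center: np.ndarray | None = field(default=None, repr=False)
    col_scale: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.I * self.J

    @property
    def dim(self) -> int:
        return self.weights.shape[2]

    def flat_weights(self) -> np.ndarray:
        """Weights as an (I*J, d) array, node (i, j) at linear index i*J + j."""
        return self.weights.reshape(self.n_nodes, self.dim)

    def node_occupancy(self) -> np.ndarray:
        """Fragment count per node, shape (I, J)."""
        if self.assignments is None:
            raise ValueError("model has no assignments")
        lin = self.assignments[:, 0] * self.J + self.assignments[:, 1]
        return np.bincount(lin, minlength=self.n_nodes).reshape(self.I, self.J)


def _canonical_order(values: np.ndarray) -> np.ndarray:
    """Permutation sorting rows lexicographically (column 0 primary)."""
    return np.lexsort(values.T[::-1])


def _principal_axes(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean, first two unit principal axes, and PC standard deviations."""
    mean = x.mean(axis=0)
    xc = x - mean
    # SVD of the centered matrix; deterministic sign fix (largest-|.| loading > 0)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    axes = vt[:2]
    for a in axes:
        j = np.argmax(np.abs(a))
        if a[j] < 0:
            a *= -1.0
    sds = s[:2] / np.sqrt(x.shape[0])
    return mean, axes, sds


def init_lattice(matrix, config: BLSOMConfig = BLSOMConfig()) -> BLSOMModel:
    """PCA-plane initialization of the lattice.

    The node count targets N / seqs_per_node; the aspect ratio I/J follows
    sigma1/sigma2.  The initial weight at node (i, j) is the data mean plus
    offsets along the first two principal axes spanning ``sd_multiplier``
    standard deviations per axis, centered on the mean.  Fully deterministic.
    """
    x = np.asarray(matrix.values, dtype=np.float64)
    n, d = x.shape
    if n < 2 * config.seqs_per_node:
        raise ValueError(
            f"need at least {2 * config.seqs_per_node:.0f} rows, got {n}"
        )
    x = x[_canonical_order(x)]
    col_center = col_scale = None
    if config.standardize_columns:
        col_center = x.mean(axis=0)
        col_scale = x.std(axis=0)
        col_scale[col_scale == 0] = 1.0
        x = (x - col_center) / col_scale
    mean, axes, sds = _principal_axes(x)
    sigma1, sigma2 = float(sds[0]), float(sds[1])
    if sigma1 == 0.0:
        raise ValueError("degenerate matrix: zero variance")
    n_target = max(int(round(n / config.seqs_per_node)), 2 * config.min_J)
    if sigma2 == 0.0:
        import warnings

        warnings.warn("second principal component has zero variance; J clamped")
        J = config.min_J
    else:
        J = max(config.min_J, int(round(np.sqrt(n_target * sigma2 / sigma1))))
    I = max(int(round(n_target / J)), J)
    span_i = config.sd_multiplier * sigma1
    span_j = config.sd_multiplier * sigma2
    ii = (np.arange(I) / (I - 1) - 0.5)[:, None, None]
    jj = (np.arange(J) / (J - 1) - 0.5)[None, :, None]
    weights = mean[None, None, :] + ii * span_i * axes[0] + jj * span_j * axes[1]
    return BLSOMModel(
        I=I, J=J, weights=weights, sigma1=sigma1, sigma2=sigma2, mean=mean,
        col_center=col_center, col_scale=col_scale,
    )


def _model_space(model: BLSOMModel, x: np.ndarray) -> np.ndarray:
    """Apply the model's optional column standardization to input rows."""
    if model.col_center is not None:
        return (x - model.col_center) / model.col_scale
    return x


def _bmu(x: np.ndarray, flat_w: np.ndarray) -> np.ndarray:
    """Best-matching node per row; ties go to the smallest linear index."""
    d2 = cdist(x, flat_w, metric="sqeuclidean")
    return d2.argmin(axis=1)  # argmin returns the first (smallest) index on ties


def _lattice_distances(I: int, J: int) -> np.ndarray:
    """Euclidean node-to-node distances on the lattice, (I*J, I*J)."""
    ii, jj = np.divmod(np.arange(I * J), J)
    di = ii[:, None] - ii[None, :]
    dj = jj[:, None] - jj[None, :]
    return np.sqrt(di * di + dj * dj)


def neighborhood_radius(epoch: int, epochs: int, r0: float, r1: float) -> float:
    """Linear decay from r0 (epoch 1) to r1 (final epoch)."""
    if epochs == 1:
        return r1
    frac = (epoch - 1) / (epochs - 1)
    return r0 + (r1 - r0) * frac


def train(matrix, model: BLSOMModel, config: BLSOMConfig = BLSOMConfig()) -> BLSOMModel:
    """Batch-train the lattice on a composition matrix.

    Each epoch: (1) every fragment is assigned to its best-matching node by
    Euclidean distance; (2) every node's weight becomes the kernel-weighted
    mean of fragments assigned within lattice radius r(t), with a Gaussian
    kernel exp(-d^2 / 2 r^2) truncated at d > r.  Nodes receiving zero
    kernel mass keep their previous weight.  The result is independent of
    the fragment input order.
    """
    x = np.asarray(matrix.values, dtype=np.float64)
    if x.shape[1] != model.dim:
        raise ValueError(
            f"matrix dimension {x.shape[1]} does not match model dimension {model.dim}"
        )
    xs = _model_space(model, x[_canonical_order(x)])
    flat_w = model.flat_weights().copy()
    n_nodes = model.n_nodes
    lat_d = _lattice_distances(model.I, model.J)
    r0 = (
        config.neighborhood_initial_radius
        if config.neighborhood_initial_radius is not None
        else max(model.I, model.J) / 2.0
    )
    r1 = config.neighborhood_final_radius
    for epoch in range(1, config.epochs + 1):
        bmu = _bmu(xs, flat_w)
        sums = np.zeros((n_nodes, model.dim))
        np.add.at(sums, bmu, xs)
        counts = np.bincount(bmu, minlength=n_nodes).astype(np.float64)
        r = neighborhood_radius(epoch, config.epochs, r0, r1)
        if r <= 0:
            kernel = np.eye(n_nodes)
        else:
            kernel = np.exp(-(lat_d**2) / (2.0 * r * r))
            kernel[lat_d > r] = 0.0
        num = kernel @ sums
        den = kernel @ counts
        occupied = den > 0
        flat_w[occupied] = num[occupied] / den[occupied, None]
    trained = replace(
        model,
        weights=flat_w.reshape(model.I, model.J, model.dim),
        trained=True,
    )
    trained.assignments = assign(matrix, trained)
    return trained


def assign(matrix, model: BLSOMModel) -> np.ndarray:
    """Best-matching node per fragment, as an (N, 2) array of (i, j).

    Euclidean metric; ties break toward the smallest linear index i*J + j.
    """
    x = np.asarray(matrix.values, dtype=np.float64)
    if x.shape[1] != model.dim:
        raise ValueError("matrix dimension does not match model")
    lin = _bmu(_model_space(model, x), model.flat_weights())
    return np.stack(np.divmod(lin, model.J), axis=1)


def save_model(model: BLSOMModel, directory, fragments=None) -> None:
    """Serialize a model to a directory: meta.json, weights.tsv, assignments.tsv."""
    import json
    from pathlib import Path

    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "I": model.I,
        "J": model.J,
        "dim": model.dim,
        "sigma1": model.sigma1,
        "sigma2": model.sigma2,
        "trained": model.trained,
        "standardized": model.col_center is not None,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    np.savetxt(directory / "weights.tsv", model.flat_weights(), delimiter="\t")
    np.savetxt(directory / "mean.tsv", model.mean[None, :], delimiter="\t")
    if model.col_center is not None:
        np.savetxt(
            directory / "standardization.tsv",
            np.vstack([model.col_center, model.col_scale]),
            delimiter="\t",
        )
    if model.assignments is not None:
        df = pd.DataFrame(model.assignments, columns=["i", "j"])
        if fragments is not None:
            df = pd.concat([fragments.reset_index(drop=True), df], axis=1)
        df.to_csv(directory / "assignments.tsv", sep="\t", index=False)


def load_model(directory) -> BLSOMModel:
    """Load a model serialized by :func:`save_model`."""
    import json
    from pathlib import Path

    import pandas as pd

    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    flat = np.loadtxt(directory / "weights.tsv", delimiter="\t", ndmin=2)
    mean = np.loadtxt(directory / "mean.tsv", delimiter="\t", ndmin=2)[0]
    col_center = col_scale = None
    if meta.get("standardized"):
        std = np.loadtxt(directory / "standardization.tsv", delimiter="\t", ndmin=2)
        col_center, col_scale = std[0], std[1]
    assignments = None
    apath = directory / "assignments.tsv"
    if apath.exists():
        adf = pd.read_csv(apath, sep="\t")
        assignments = adf[["i", "j"]].to_numpy(dtype=np.int64)
    return BLSOMModel(
        I=int(meta["I"]),
        J=int(meta["J"]),
        weights=flat.reshape(int(meta["I"]), int(meta["J"]), int(meta["dim"])),
        sigma1=float(meta["sigma1"]),
        sigma2=float(meta["sigma2"]),
        mean=mean,
        trained=bool(meta["trained"]),
        assignments=assignments,
        col_center=col_center,
        col_scale=col_scale,
    )
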