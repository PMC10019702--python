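"""Structural connectomes: synthesis, Gaussian weight resampling, normalization, I/O.

The coupling scaffold of the whole-brain model is a nonnegative region-by-region
matrix ``C`` whose rows each sum to 1, so the coupling term for a region is a
weighted average over its structural neighbours.  Group-consensus connectomes in
this tradition are built by keeping edges whose presence across individual
tractograms exceeds a consistency cutoff, then rank-resampling the surviving
streamline densities onto a Gaussian (mu=0.5, sigma=0.15) before row
normalization.  Lacking diffusion data, :func:`generate_synthetic_connectome`
emulates the same construction from a pseudo-subject presence/weight model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "StructuralConnectome",
    "generate_synthetic_connectome",
    "gaussian_resample_weights",
    "normalize_rows",
    "read_connectome",
    "write_connectome",
]


@dataclass
class StructuralConnectome:
    """Row-normalized nonnegative coupling matrix with region labels."""

    weights: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("connectome weights must be a square matrix")
        if not self.region_labels:
            self.region_labels = [f"region_{i:03d}" for i in range(self.n_regions)]
        if len(self.region_labels) != self.n_regions:
            raise ValueError("number of labels must match matrix dimension")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def validate(self, *, normalized: bool = True) -> None:
        w = self.weights
        if not np.all(np.isfinite(w)):
            raise ValueError("connectome contains non-finite weights")
        if np.any(np.diag(w) != 0):
            raise ValueError("connectome diagonal must be exactly zero")
        if np.any(w < 0):
            raise ValueError("connectome weights must be nonnegative")
        if normalized:
            sums = w.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
            if bad.size:
                raise ValueError(
                    f"rows not normalized to 1: {[self.region_labels[i] for i in bad[:5]]}"
                )


def gaussian_resample_weights(
    weights: np.ndarray, mu: float = 0.5, sigma: float = 0.15
) -> np.ndarray:
    """Rank-based inverse-normal transform of positive edge weights.

    Weight with (average, tie-aware) rank r among n maps to
    ``mu + sigma * Phi^{-1}((r - 0.5) / n)``; output is clipped below at 1e-6 so
    coupling weights stay positive.  Ordering of distinct inputs is preserved.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("cannot resample an empty weight vector")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ranks = stats.rankdata(w, method="average")
    out = mu + sigma * stats.norm.ppf((ranks - 0.5) / w.size)
    return np.clip(out, 1e-6, None)


def normalize_rows(weights: np.ndarray) -> np.ndarray:
    """Divide each row by its sum so every region's couplings sum to 1."""
    w = np.asarray(weights, dtype=float)
    sums = w.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        raise ValueError(f"row(s) with zero total connectivity: regions {bad.tolist()}")
    return w / sums[:, None]


def edges_above_consistency(
    n_present: np.ndarray, n_subjects: int, threshold: float
) -> np.ndarray:
    """Strictly-above consistency rule: an edge present in exactly the
    threshold fraction of subjects is dropped."""
    return np.asarray(n_present) > threshold * n_subjects


def generate_synthetic_connectome(
    n_regions: int = 68,
    n_pseudo_subjects: int = 100,
    edge_presence_prob: float = 0.7,
    consistency_threshold: float = 0.6,
    seed: int = 0,
) -> StructuralConnectome:
    """Emulate a group-consensus connectome from a pseudo-subject edge model.

    Each pseudo-subject contributes a symmetric set of present edges (Bernoulli
    per undirected pair) with positive log-normal weights.  Edges present in
    strictly more than ``consistency_threshold`` of pseudo-subjects survive;
    surviving weights are averaged over the subjects that express them,
    rank-resampled onto a Gaussian (mu=0.5, sigma=0.15), and row-normalized.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if not 0.0 < consistency_threshold < 1.0:
        raise ValueError("consistency_threshold must lie in (0, 1)")
    if not 0.0 < edge_presence_prob <= 1.0:
        raise ValueError("edge_presence_prob must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_regions, k=1)
    n_edges = iu.size

    presence = rng.random((n_pseudo_subjects, n_edges)) < edge_presence_prob
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=(n_pseudo_subjects, n_edges))
    n_present = presence.sum(axis=0)
    keep = edges_above_consistency(n_present, n_pseudo_subjects, consistency_threshold)
    with np.errstate(invalid="ignore"):
        mean_w = np.where(
            keep, (raw * presence).sum(axis=0) / np.maximum(n_present, 1), 0.0
        )

    averaged = np.zeros((n_regions, n_regions))
    averaged[iu, ju] = mean_w
    averaged += averaged.T

    labels = [f"region_{i:03d}" for i in range(n_regions)]
    degree = (averaged > 0).sum(axis=1)
    empty = np.flatnonzero(degree == 0)
    if empty.size:
        raise ValueError(
            f"region(s) left with no surviving edges: {[labels[i] for i in empty]}"
        )

    kept_idx = np.flatnonzero(mean_w > 0)
    resampled = gaussian_resample_weights(mean_w[kept_idx])
    sym = np.zeros_like(averaged)
    sym[iu[kept_idx], ju[kept_idx]] = resampled
    sym += sym.T

    conn = StructuralConnectome(normalize_rows(sym), labels)
    conn.validate()
    return conn


def write_connectome(conn: StructuralConnectome, path: str | Path) -> None:
    """Write as TSV with a region-label header row and first column."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("region\t" + "\t".join(conn.region_labels) + "\n")
        for label, row in zip(conn.region_labels, conn.weights):
            fh.write(label + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_connectome(path: str | Path) -> StructuralConnectome:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows, labels = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    weights = np.asarray(rows, dtype=float)
    if weights.shape[0] != weights.shape[1] or labels != header:
        raise ValueError(f"{path}: connectome file is not a labelled square matrix")
    if np.any(weights < 0):
        raise ValueError(f"{path}: negative weights are not a valid connectome")
    return StructuralConnectome(weights, labels)
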