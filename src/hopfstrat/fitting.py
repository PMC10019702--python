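"""Grid-search fitting with Monte-Carlo nonparametric resampling.

The model is fit by simulating every point of an (A, G, F, M) grid once,
reducing each simulation to a Fisher-z FC plus its Kuramoto synchrony and
metastability, then repeatedly (Monte-Carlo) drawing a fraction of subjects,
averaging their Fisher-z FCs, and recording the grid point whose simulated FC
best correlates with the draw's average (upper-triangle Pearson).  Pooling the
per-iteration optima over three subject fractions (30/50/70%, 500 iterations
each by default) yields a distribution over grid points; a bimodal distribution
signals two covert dynamical subtypes, extracted here by deterministic 2-means
over step-scaled parameter vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

from ._utils import content_hash, derive_seed
from .connectome import StructuralConnectome
from .metrics import kuramoto_order_series, metastability, synchrony
from .oscillator import ModelParameters, SimulationConfig, extract_bold, simulate_network
from .signals import FCMatrix, bandpass_dct, compute_fc, fc_similarity, fisher_z, group_average_fc

__all__ = [
    "AxisRange",
    "ParameterGrid",
    "GridSimBank",
    "MonteCarloRecord",
    "SubtypeSolution",
    "build_parameter_grid",
    "published_grid",
    "simulate_grid",
    "monte_carlo_fit",
    "detect_modes",
]

logger = logging.getLogger(__name__)

#: the published search ranges: (start, stop, step) per axis
PUBLISHED_RANGES = {
    "A": (-0.2, 0.2, 0.01),
    "G": (0.005, 0.05, 0.005),
    "F": (0.0, 1.0, 0.1),
    "M": (0.10, 0.50, 0.03),
}


@dataclass(frozen=True)
class AxisRange:
    start: float
    stop: float
    step: float

    def values(self) -> np.ndarray:
        """Inclusive arithmetic sequence with half-step tolerance at the top."""
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.stop < self.start:
            raise ValueError("stop must be >= start")
        n = int(np.floor((self.stop - self.start) / self.step + 0.5)) + 1
        # round away float-accumulation dust so grid values compare exactly
        return np.round(self.start + self.step * np.arange(n), 10)


@dataclass
class ParameterGrid:
    """Cartesian product of four axis ranges, enumerated in (A, G, F, M)
    lexicographic order."""

    a_range: AxisRange
    g_range: AxisRange
    f_range: AxisRange
    m_range: AxisRange
    beta: float = 0.02

    @property
    def axis_values(self) -> dict[str, np.ndarray]:
        return {
            "A": self.a_range.values(),
            "G": self.g_range.values(),
            "F": self.f_range.values(),
            "M": self.m_range.values(),
        }

    @property
    def steps(self) -> dict[str, float]:
        return {
            "A": self.a_range.step,
            "G": self.g_range.step,
            "F": self.f_range.step,
            "M": self.m_range.step,
        }

    def __len__(self) -> int:
        return int(np.prod([v.size for v in self.axis_values.values()]))

    def points(self) -> list[ModelParameters]:
        av = self.axis_values
        return [
            ModelParameters(float(a), float(g), float(f), float(m), self.beta)
            for a, g, f, m in product(av["A"], av["G"], av["F"], av["M"])
        ]


def build_parameter_grid(
    a_range: tuple[float, float, float],
    g_range: tuple[float, float, float],
    f_range: tuple[float, float, float],
    m_range: tuple[float, float, float],
    beta: float = 0.02,
) -> ParameterGrid:
    return ParameterGrid(
        AxisRange(*a_range), AxisRange(*g_range), AxisRange(*f_range), AxisRange(*m_range), beta
    )


def published_grid() -> ParameterGrid:
    """The published search grid (41 x 10 x 11 x 14 = 63,140 points)."""
    return build_parameter_grid(*(PUBLISHED_RANGES[k] for k in ("A", "G", "F", "M")))


@dataclass
class GridSimBank:
    """One simulated FC (fisher_z) + dynamics metrics per grid point.

    Points are stored in the grid's lexicographic order, so index-based
    argmax with first-hit tie-breaking selects the lexicographically smallest
    winner.
    """

    grid: ParameterGrid
    points: list[ModelParameters]
    fcs: list[FCMatrix]
    synchrony: np.ndarray
    metastability: np.ndarray
    master_seed: int = 0

    def __len__(self) -> int:
        return len(self.points)

    def index_of(self, params: ModelParameters) -> int:
        target = tuple(np.round(params.as_tuple(), 10))
        for i, p in enumerate(self.points):
            if tuple(np.round(p.as_tuple(), 10)) == target:
                return i
        raise ValueError(f"{params} is not a grid point of this bank")

    def upper_triangles(self) -> np.ndarray:
        """(n_points, n_pairs) matrix of FC upper triangles."""
        return np.vstack([fc.upper_triangle() for fc in self.fcs])


def _simulate_point(
    params: ModelParameters,
    connectome: StructuralConnectome,
    omega0: np.ndarray,
    config: SimulationConfig,
    seeds: Sequence[int],
) -> tuple[np.ndarray, float, float]:
    """Reduce one grid point to its (ensemble-averaged) Fisher-z FC + metrics.

    With several seeds the FC approximates the model's expected FC at that
    point — the quantity a group-averaged empirical FC should be compared to —
    rather than a single noise realization; metrics are averaged likewise.
    """
    fcz_sum = None
    syn = met = 0.0
    for seed in seeds:
        cfg = SimulationConfig(
            config.dt, config.duration, config.burn_in, config.sample_interval, seed
        )
        traj = simulate_network(params, connectome, omega0, cfg)
        bold = extract_bold(traj)
        fcz = fisher_z(compute_fc(bandpass_dct(bold))).values
        fcz_sum = fcz if fcz_sum is None else fcz_sum + fcz
        r = kuramoto_order_series(traj)
        syn += synchrony(r)
        met += metastability(r)
    k = len(seeds)
    return fcz_sum / k, syn / k, met / k


def simulate_grid(
    grid: ParameterGrid,
    connectome: StructuralConnectome,
    omega0: np.ndarray,
    config: SimulationConfig,
    n_workers: int = 1,
    cache_dir: str | Path | None = None,
    n_ensemble: int = 1,
) -> GridSimBank:
    """Simulate every grid point and reduce it to FC + dynamics metrics.

    ``n_ensemble`` independent-noise simulations per point are averaged in
    Fisher-z space; with 1 (the default) each point is a single realization.
    Per-point noise seeds derive from (master seed, grid index, replicate), so
    the bank is identical regardless of worker count.  With ``cache_dir`` set,
    the bank is stored on disk keyed by a content hash of grid, connectome,
    frequencies and config, and reloaded on repeat calls.
    """
    points = grid.points()
    key = None
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        key = content_hash(
            [p.as_tuple() + (p.beta,) for p in points],
            connectome.weights,
            omega0,
            (config.dt, config.duration, config.burn_in, config.sample_interval, config.seed),
            n_ensemble,
        )
        cache_file = cache_dir / f"gridbank_{key[:16]}.npz"
        if cache_file.exists():
            logger.info("grid bank cache hit: %s", cache_file)
            dat = np.load(cache_file)
            fcs = [
                FCMatrix(dat["fc"][i], "fisher_z", {"kind": "simulated", "params": points[i].as_tuple()})
                for i in range(len(points))
            ]
            return GridSimBank(grid, points, fcs, dat["syn"], dat["met"], config.seed)

    seeds = [
        [derive_seed(config.seed, 7001, i, rep) for rep in range(n_ensemble)]
        for i in range(len(points))
    ]
    results = Parallel(n_jobs=n_workers)(
        delayed(_simulate_point)(p, connectome, omega0, config, s)
        for p, s in zip(points, seeds)
    )
    fc_arrays = np.stack([r[0] for r in results])
    syn = np.array([r[1] for r in results])
    met = np.array([r[2] for r in results])
    if cache_dir is not None and key is not None:
        np.savez_compressed(
            cache_dir / f"gridbank_{key[:16]}.npz", fc=fc_arrays, syn=syn, met=met
        )
    fcs = [
        FCMatrix(fc_arrays[i], "fisher_z", {"kind": "simulated", "params": points[i].as_tuple()})
        for i in range(len(points))
    ]
    return GridSimBank(grid, points, fcs, syn, met, config.seed)


@dataclass
class MonteCarloRecord:
    iteration: int
    threshold: float
    selected_subjects: list[str]
    best_params: ModelParameters
    best_similarity: float


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def monte_carlo_fit(
    bank: GridSimBank,
    subject_fcs: Sequence[FCMatrix],
    thresholds: Sequence[float] = (0.3, 0.5, 0.7),
    iters_per_threshold: int = 500,
    seed: int = 0,
) -> list[MonteCarloRecord]:
    """Monte-Carlo nonparametric fit: per iteration, draw a subject fraction,
    average their Fisher-z FCs, and record the best-matching grid point.

    Subjects are sorted by id before drawing so the result is invariant to the
    order of ``subject_fcs``.  Ties in the argmax resolve to the
    lexicographically smallest grid point (with a logged warning).
    """
    if len(subject_fcs) == 0:
        raise ValueError("no subject FCs")
    if len(bank) == 0:
        raise ValueError("empty grid bank")
    for fc in subject_fcs:
        if fc.space != "fisher_z":
            raise ValueError("subject FCs must be fisher_z")

    ids = [
        fc.provenance.get("subject_id") or f"subject_{i:03d}"
        for i, fc in enumerate(subject_fcs)
    ]
    order = np.argsort(ids)  # stable id sort -> permutation invariance
    ids_sorted = [ids[i] for i in order]
    fcs_sorted = [subject_fcs[i] for i in order]
    n = len(fcs_sorted)

    # precompute normalized bank triangles: similarity reduces to a dot product
    tri = bank.upper_triangles()
    tri = tri - tri.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(tri, axis=1)
    if np.any(norms == 0):
        raise ValueError("a bank FC has a constant upper triangle")
    tri /= norms[:, None]
    subj_tri = np.vstack([fc.upper_triangle() for fc in fcs_sorted])

    records: list[MonteCarloRecord] = []
    for t_idx, thr in enumerate(thresholds):
        n_sel = _round_half_up(thr * n)
        if n_sel < 2:
            raise ValueError(
                f"threshold {thr} selects {n_sel} subject(s); need at least 2"
            )
        for it in range(iters_per_threshold):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, 5003, t_idx, it])
            )
            chosen = rng.choice(n, size=n_sel, replace=False)
            avg = subj_tri[chosen].mean(axis=0)
            avg = avg - avg.mean()
            nrm = np.linalg.norm(avg)
            if nrm == 0:
                raise ValueError("degenerate (constant) group-average FC")
            sims = tri @ (avg / nrm)
            best = int(np.argmax(sims))
            if np.count_nonzero(sims == sims[best]) > 1:
                logger.warning(
                    "similarity tie at iteration %d (threshold %g); "
                    "keeping lexicographically smallest grid point", it, thr
                )
            records.append(
                MonteCarloRecord(
                    iteration=it,
                    threshold=float(thr),
                    selected_subjects=[ids_sorted[c] for c in chosen],
                    best_params=bank.points[best],
                    best_similarity=float(sims[best]),
                )
            )
    return records


@dataclass
class SubtypeSolution:
    """The two modal parameter sets with their simulated FCs and metrics."""

    params_dep1: ModelParameters
    params_dep2: ModelParameters
    fc_dep1: FCMatrix
    fc_dep2: FCMatrix
    metastability_dep1: float
    metastability_dep2: float
    synchrony_dep1: float
    synchrony_dep2: float
    mode_counts: dict[str, int]
    label_rule: str = "DEP1 = mode with smaller A (ties: larger F, then larger M)"


def _two_means(points: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 2-means: farthest-point initialization, Lloyd updates.

    Returns a 0/1 label per row.  Operates on a small set of unique scaled
    grid points, so brute-force distance computation is fine.
    """
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    centers = points[[min(i, j), max(i, j)]].astype(float)
    labels = np.zeros(len(points), dtype=int)
    for _ in range(max_iter):
        dist = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        new_labels = np.argmin(dist, axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for c in (0, 1):
            if np.any(labels == c):
                centers[c] = points[labels == c].mean(axis=0)
    return labels


def detect_modes(records: Sequence[MonteCarloRecord], bank: GridSimBank) -> SubtypeSolution:
    """Split the pooled Monte-Carlo optima into two modes and label them.

    Parameter vectors are scaled by their axis steps (so each axis contributes
    comparably), partitioned by deterministic 2-means, and each mode is
    represented by its most frequently selected grid point (ties resolve to the
    lexicographically smallest).  DEP1 is the representative with the smaller
    bifurcation parameter A (the published subtype ordering).
    """
    if len(records) == 0:
        raise ValueError("no Monte-Carlo records")
    selected = [r.best_params for r in records]
    uniq = sorted(set(selected))
    if len(uniq) < 2:
        raise ValueError("unimodal solution; no stratification possible")

    steps = bank.grid.steps
    scale = np.array([steps["A"], steps["G"], steps["F"], steps["M"]])
    uniq_arr = np.array([p.as_tuple() for p in uniq]) / scale
    labels = _two_means(uniq_arr)
    if labels.min() == labels.max():  # degenerate split; force farthest pair apart
        raise ValueError("unimodal solution; no stratification possible")

    counts = {p: selected.count(p) for p in uniq}
    reps = []
    for c in (0, 1):
        members = [p for p, lab in zip(uniq, labels) if lab == c]
        top = max(counts[p] for p in members)
        reps.append(min(p for p in members if counts[p] == top))
    cluster_sizes = {
        c: sum(counts[p] for p, lab in zip(uniq, labels) if lab == c) for c in (0, 1)
    }

    idx = [bank.index_of(r) for r in reps]
    # DEP1 = the mode with the smaller bifurcation parameter A (ties: larger F,
    # then larger M) — the parameter ordering that separates the two published
    # subtypes (DEP1: smaller A/G, larger F/M).
    key0 = (reps[0].A, -reps[0].F, -reps[0].M)
    key1 = (reps[1].A, -reps[1].F, -reps[1].M)
    order = [0, 1] if key0 <= key1 else [1, 0]
    p1, p2 = reps[order[0]], reps[order[1]]
    i1, i2 = idx[order[0]], idx[order[1]]
    return SubtypeSolution(
        params_dep1=p1,
        params_dep2=p2,
        fc_dep1=bank.fcs[i1],
        fc_dep2=bank.fcs[i2],
        metastability_dep1=float(bank.metastability[i1]),
        metastability_dep2=float(bank.metastability[i2]),
        synchrony_dep1=float(bank.synchrony[i1]),
        synchrony_dep2=float(bank.synchrony[i2]),
        mode_counts={"DEP1": cluster_sizes[order[0]], "DEP2": cluster_sizes[order[1]]},
    )
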