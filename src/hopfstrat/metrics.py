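"""Subject-to-subtype assignment and Kuramoto synchrony/metastability.

The Kuramoto order parameter R(t) = |mean_j exp(i*theta_j(t))| measures the
instantaneous phase alignment of the N regional oscillators.  Its time mean is
the network's synchrony (in [0, 1]) and its temporal standard deviation its
metastability — the tendency to wander between alignment and dispersion.
Phases come from arg(z) for simulated trajectories; for empirical BOLD-only
input they come from the analytic-signal (Hilbert) phase of band-passed series,
which is flagged in the returned provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .oscillator import StateTrajectory
from .signals import FCMatrix, RegionalTimeSeries, fc_similarity

__all__ = [
    "SubjectAssignment",
    "assign_subjects",
    "kuramoto_order_series",
    "kuramoto_order_from_bold",
    "synchrony",
    "metastability",
    "zscore_against_distribution",
]

logger = logging.getLogger(__name__)


@dataclass
class SubjectAssignment:
    subject_id: str
    subtype: str  # "DEP1" | "DEP2"
    sim_dep1: float
    sim_dep2: float

    @property
    def margin(self) -> float:
        return abs(self.sim_dep1 - self.sim_dep2)


def assign_subjects(subject_fcs: Sequence[FCMatrix], solution) -> list[SubjectAssignment]:
    """Assign each subject to the subtype whose model FC it better matches.

    Ties go to DEP1 (with a logged warning).  Deterministic and independent of
    subject order.
    """
    out = []
    for i, fc in enumerate(subject_fcs):
        sid = fc.provenance.get("subject_id") or f"subject_{i:03d}"
        s1 = fc_similarity(fc, solution.fc_dep1)
        s2 = fc_similarity(fc, solution.fc_dep2)
        if s1 == s2:
            logger.warning("subject %s: similarity tie; assigning DEP1", sid)
        out.append(SubjectAssignment(sid, "DEP1" if s1 >= s2 else "DEP2", s1, s2))
    return out


def kuramoto_order_series(traj: StateTrajectory) -> np.ndarray:
    """R(t) from the oscillator phases arg(z_j(t))."""
    if traj.z.shape[0] < 2:
        raise ValueError("Kuramoto order needs at least 2 regions")
    theta = np.angle(traj.z)
    return np.abs(np.exp(1j * theta).mean(axis=0))


def kuramoto_order_from_bold(ts: RegionalTimeSeries) -> np.ndarray:
    """R(t) from Hilbert analytic-signal phases of (band-passed) BOLD."""
    if ts.n_regions < 2:
        raise ValueError("Kuramoto order needs at least 2 regions")
    x = ts.values - ts.values.mean(axis=1, keepdims=True)
    theta = np.angle(hilbert(x, axis=1))
    return np.abs(np.exp(1j * theta).mean(axis=0))


def synchrony(R: np.ndarray) -> float:
    """Time mean of the Kuramoto order parameter."""
    R = np.asarray(R, dtype=float)
    if R.size == 0:
        raise ValueError("empty order-parameter series")
    return float(R.mean())


def metastability(R: np.ndarray) -> float:
    """Temporal (population) standard deviation of the order parameter."""
    R = np.asarray(R, dtype=float)
    if R.size == 0:
        raise ValueError("empty order-parameter series")
    return float(R.std(ddof=0))


def zscore_against_distribution(value: float, reference: np.ndarray) -> float:
    """(value - mean(ref)) / population SD(ref); e.g. a subtype's metric
    referenced to the metric over all Monte-Carlo-selected grid points."""
    ref = np.asarray(reference, dtype=float)
    sd = ref.std(ddof=0)
    if sd == 0:
        raise ValueError("reference distribution has zero standard deviation")
    return float((value - ref.mean()) / sd)
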