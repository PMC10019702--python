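"""Band-pass filtering, functional connectivity, Fisher z, and spectral peaks.

Functional connectivity (FC) is the Pearson correlation of band-passed
(0.008-0.1 Hz) regional BOLD series.  FC matrices are Fisher z-transformed
(arctanh) before any averaging or between-matrix correlation, and model fit is
scored as the Pearson correlation of strict upper triangles.  Region-specific
intrinsic angular frequencies are the Welch spectral-density peaks within the
same band, summarized as the median across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.fft import dct, idct

__all__ = [
    "RegionalTimeSeries",
    "FCMatrix",
    "bandpass_dct",
    "compute_fc",
    "fisher_z",
    "fc_similarity",
    "group_average_fc",
    "estimate_intrinsic_frequencies",
]

BAND = (0.008, 0.1)  # Hz
FISHER_CLIP = 0.999999


@dataclass
class RegionalTimeSeries:
    """N x T real matrix of regional signals sampled every ``sample_interval`` s."""

    values: np.ndarray
    sample_interval: float
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] < 8:
            raise ValueError("need at least 8 time points")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class FCMatrix:
    """Symmetric region-by-region connectivity, raw correlation or Fisher z."""

    values: np.ndarray
    space: str = "raw-correlation"  # or "fisher_z"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("FC matrix must be square")
        if self.space not in ("raw-correlation", "fisher_z"):
            raise ValueError(f"unknown FC space {self.space!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("FC matrix must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]


def _dct_frequencies(n: int, sample_interval: float) -> np.ndarray:
    # DCT-II coefficient k corresponds to frequency k / (2 * n * dt)
    return np.arange(n) / (2.0 * n * sample_interval)


def bandpass_dct(
    ts: RegionalTimeSeries, f_low: float = BAND[0], f_high: float = BAND[1]
) -> RegionalTimeSeries:
    """Band-pass via DCT windowing over the full series length.

    Forward type-II DCT (orthonormal), zero every coefficient whose equivalent
    frequency lies outside [f_low, f_high], inverse transform.  The DC
    coefficient sits below any positive f_low, so the mean is removed.
    """
    nyquist = 1.0 / (2.0 * ts.sample_interval)
    if not 0 <= f_low < f_high:
        raise ValueError("need 0 <= f_low < f_high")
    if f_high >= nyquist:
        raise ValueError(f"f_high={f_high} Hz is at/above Nyquist {nyquist} Hz")
    coef = dct(ts.values, type=2, norm="ortho", axis=1)
    freqs = _dct_frequencies(ts.n_samples, ts.sample_interval)
    coef[:, (freqs < f_low) | (freqs > f_high)] = 0.0
    out = idct(coef, type=2, norm="ortho", axis=1)
    return RegionalTimeSeries(out, ts.sample_interval, ts.subject_id)


def compute_fc(ts: RegionalTimeSeries) -> FCMatrix:
    """Pearson correlation among all region pairs (diagonal 1)."""
    sd = ts.values.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance region(s): {dead.tolist()}")
    r = np.corrcoef(ts.values)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    prov = {"kind": "empirical", "subject_id": ts.subject_id} if ts.subject_id else {}
    return FCMatrix(r, "raw-correlation", prov)


def fisher_z(fc: FCMatrix) -> FCMatrix:
    """Variance-stabilizing arctanh transform; diagonal set to 0."""
    if fc.space != "raw-correlation":
        raise ValueError("fisher_z expects a raw-correlation FC (applied twice?)")
    z = np.arctanh(np.clip(fc.values, -FISHER_CLIP, FISHER_CLIP))
    np.fill_diagonal(z, 0.0)
    return FCMatrix(z, "fisher_z", dict(fc.provenance))


def fc_similarity(a: FCMatrix, b: FCMatrix) -> float:
    """Pearson correlation of the strict upper triangles of two FCs."""
    if a.n_regions != b.n_regions:
        raise ValueError("FC dimension mismatch")
    if a.space != b.space:
        raise ValueError(f"FC space mismatch: {a.space} vs {b.space}")
    return float(np.corrcoef(a.upper_triangle(), b.upper_triangle())[0, 1])


def group_average_fc(fcs: Sequence[FCMatrix]) -> FCMatrix:
    """Entrywise mean of Fisher-z FCs (the per-iteration group map)."""
    if len(fcs) == 0:
        raise ValueError("cannot average an empty FC list")
    n = fcs[0].n_regions
    for fc in fcs:
        if fc.space != "fisher_z":
            raise ValueError("group averaging requires fisher_z FCs")
        if fc.n_regions != n:
            raise ValueError("FC dimension mismatch in group average")
    mean = np.mean([fc.values for fc in fcs], axis=0)
    return FCMatrix(mean, "fisher_z", {"kind": "group_average", "n": len(fcs)})


def welch_peak_frequency(
    x: np.ndarray,
    sample_interval: float,
    f_low: float = BAND[0],
    f_high: float = BAND[1],
    segment_length: int = 64,
) -> float:
    """Peak (Hz) of the Welch spectral density restricted to [f_low, f_high]."""
    x = np.asarray(x, dtype=float)
    nperseg = min(x.size, segment_length)
    freqs, pxx = sps.welch(
        x,
        fs=1.0 / sample_interval,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
    )
    in_band = (freqs >= f_low) & (freqs <= f_high)
    if not np.any(in_band):
        raise ValueError(
            "series too short: no spectral bins inside the frequency band"
        )
    return float(freqs[in_band][np.argmax(pxx[in_band])])


def estimate_intrinsic_frequencies(
    cohort_ts: Sequence[RegionalTimeSeries],
    f_low: float = BAND[0],
    f_high: float = BAND[1],
    segment_length: int = 64,
) -> np.ndarray:
    """Per-region intrinsic angular frequency omega0 (rad/s).

    For every subject and region the Welch periodogram peak inside the band is
    found (segment length min(T, 64), 50% overlap, cosine taper); the median
    across subjects is returned per region.
    """
    if len(cohort_ts) == 0:
        raise ValueError("empty cohort")
    n = cohort_ts[0].n_regions
    dt = cohort_ts[0].sample_interval
    for ts in cohort_ts:
        if ts.n_regions != n or ts.sample_interval != dt:
            raise ValueError("all subjects must share region count and sampling")
    peaks = np.empty((len(cohort_ts), n))
    for s, ts in enumerate(cohort_ts):
        for j in range(n):
            peaks[s, j] = welch_peak_frequency(
                ts.values[j], dt, f_low, f_high, segment_length
            )
    return 2.0 * np.pi * np.median(peaks, axis=0)
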