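"""Connectome-coupled oscillators with amplitude and adaptive frequency dynamics.

Each of the N cortical regions is a Stuart-Landau (normal-form Hopf) oscillator
whose complex amplitude z_j and angular frequency omega_j evolve as

    dz_j/dt     = (A + i*omega_j - |z_j|^2) z_j
                  + G * sum_i C_ij (z_i - z_j) + beta * eta_j
    domega_j/dt = omega0_j - F*omega_j + M * sum_i C_ij arg(z_i)

with C the row-normalized structural connectome, A the global bifurcation
parameter (A < 0: damped stable focus; A > 0: limit cycle of radius sqrt(A)),
G the global coupling, F the global feedback coefficient pulling omega_j back
toward omega0_j/F, and M the global modulation index weighting the mean phase
of structural neighbours.  eta_j is complex white noise (independent real and
imaginary components) entering the amplitude equation only; the frequency
equation is deterministic.  Re{z} is the simulated BOLD-like signal; Im{z} is
an unobservable hidden state.

Integration is Euler-Maruyama at a step dt far below the fastest intrinsic
period (2*pi/0.221 ~ 28 s), sampling at the scanner TR after a burn-in that
discards initial transients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectome import StructuralConnectome

__all__ = [
    "ModelParameters",
    "SimulationConfig",
    "StateTrajectory",
    "SimulationDivergedError",
    "draw_intrinsic_frequencies",
    "simulate_network",
    "extract_bold",
]

logger = logging.getLogger(__name__)

OMEGA0_RANGE = (0.098, 0.221)  # rad/s; dominant resting BOLD band


@dataclass(frozen=True, order=True)
class ModelParameters:
    """One point of the (A, G, F, M) control space, plus the noise SD beta.

    Ordering is lexicographic in (A, G, F, M), which defines the deterministic
    tie-break used throughout the fitting stage.
    """

    A: float
    G: float
    F: float
    M: float
    beta: float = 0.02

    def __post_init__(self) -> None:
        if self.G < 0 or self.F < 0 or self.M < 0 or self.beta < 0:
            raise ValueError("G, F, M and beta must be nonnegative")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.A, self.G, self.F, self.M)


@dataclass(frozen=True)
class SimulationConfig:
    """Integration-step, duration and sampling settings (all in seconds)."""

    dt: float = 0.05
    duration: float = 420.0  # 7-minute resting-state scan
    burn_in: float = 60.0
    sample_interval: float = 2.0  # TR
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dt, self.duration, self.burn_in, self.sample_interval) <= 0:
            raise ValueError("all timing settings must be positive")
        if self.dt >= self.sample_interval:
            raise ValueError("dt must be smaller than sample_interval")
        if self.burn_in >= self.duration:
            raise ValueError("burn_in must be shorter than duration")


@dataclass
class StateTrajectory:
    """Sampled states: complex z (N x T), omega (N x T), sample times (T,)."""

    z: np.ndarray
    omega: np.ndarray
    times: np.ndarray
    sample_interval: float
    params: ModelParameters | None = None


class SimulationDivergedError(RuntimeError):
    pass


def draw_intrinsic_frequencies(
    n_regions: int,
    seed: int = 0,
    low: float = OMEGA0_RANGE[0],
    high: float = OMEGA0_RANGE[1],
) -> np.ndarray:
    """Draw region-specific intrinsic angular frequencies (rad/s), uniform in
    the empirically reported resting-state range."""
    if high <= low or low <= 0:
        raise ValueError("need 0 < low < high")
    return np.random.default_rng(seed).uniform(low, high, size=n_regions)


def simulate_network(
    params: ModelParameters,
    connectome: StructuralConnectome,
    omega0: np.ndarray,
    config: SimulationConfig,
) -> StateTrajectory:
    """Integrate the coupled amplitude/frequency network (Euler-Maruyama).

    Initial z_j are drawn uniformly from a disk of radius 0.1 (seeded) and
    omega_j start at omega0_j.  Noise increments on z have SD beta*sqrt(dt)
    per real/imaginary component per step.  States are recorded every
    ``sample_interval`` once ``burn_in`` has elapsed.
    """
    C = connectome.weights
    omega0 = np.asarray(omega0, dtype=float)
    n = C.shape[0]
    if omega0.shape != (n,):
        raise ValueError(
            f"dimension mismatch: connectome has {n} regions, omega0 has {omega0.shape}"
        )
    if np.any(omega0 <= 0):
        raise ValueError("intrinsic frequencies must be positive")
    if params.F == 0:
        logger.warning(
            "F=0: no frequency feedback; omega_j may drift over the run (remains finite)"
        )

    dt = config.dt
    n_steps = int(round(config.duration / dt))
    stride = int(round(config.sample_interval / dt))
    first = int(round(config.burn_in / dt))
    sample_steps = np.arange(first, n_steps + 1, stride)
    n_samp = sample_steps.size

    rng = np.random.default_rng(config.seed)
    # uniform on a disk of radius 0.1
    radius = 0.1 * np.sqrt(rng.random(n))
    phase = rng.uniform(0.0, 2.0 * np.pi, n)
    z = radius * np.exp(1j * phase)
    omega = omega0.copy()

    A, G, F, M, beta = params.A, params.G, params.F, params.M, params.beta
    noise_scale = beta * np.sqrt(dt)

    z_out = np.empty((n, n_samp), dtype=complex)
    om_out = np.empty((n, n_samp), dtype=float)
    sample_set = set(int(s) for s in sample_steps)
    k = 0
    if 0 in sample_set:  # burn_in > 0 by construction, never hit
        z_out[:, k], om_out[:, k] = z, omega
        k += 1

    for step in range(1, n_steps + 1):
        theta = np.angle(z)  # principal value in (-pi, pi]
        coupling = G * (C @ z - z)  # rows of C sum to 1
        drift = (A + 1j * omega - np.abs(z) ** 2) * z + coupling
        if beta > 0:
            xi = rng.standard_normal((2, n))
            z = z + dt * drift + noise_scale * (xi[0] + 1j * xi[1])
        else:
            z = z + dt * drift
        omega = omega + dt * (omega0 - F * omega + M * (C @ theta))
        if step in sample_set:
            if not (np.all(np.isfinite(z.real)) and np.all(np.isfinite(z.imag))
                    and np.all(np.isfinite(omega))):
                raise SimulationDivergedError(
                    f"non-finite state at step {step} (t={step * dt:.2f} s) "
                    f"for parameters {params}"
                )
            z_out[:, k], om_out[:, k] = z, omega
            k += 1

    times = sample_steps.astype(float) * dt
    return StateTrajectory(z_out, om_out, times, config.sample_interval, params)


def extract_bold(traj: StateTrajectory) -> "RegionalTimeSeries":
    """Simulated regional BOLD: the real part of z at the sampled times."""
    from .signals import RegionalTimeSeries

    return RegionalTimeSeries(traj.z.real.copy(), traj.sample_interval)
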