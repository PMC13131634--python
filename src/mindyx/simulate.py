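"""Forward simulation of the network model.

Noise-free iteration probes the attractor landscape; noise-driven iteration
generates surrogate neural series under a task design; the observation model
(HRF convolution plus Gaussian observation noise) turns neural trajectories
into synthetic BOLD runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MindyXParams, assemble_connectivity, step
from .preprocess import BoldRun, HRFKernel, TaskDesign

__all__ = [
    "Trajectory",
    "NoiseSpec",
    "DIVERGENCE_BOUND",
    "simulate_noise_free",
    "simulate_noise_driven",
    "generate_bold",
]

#: States with sup-norm beyond this are treated as numerically divergent.
DIVERGENCE_BOUND = 1e6


@dataclass
class Trajectory:
    """A simulated state sequence (parcels x steps, ordered in time)."""

    states: np.ndarray
    input: np.ndarray | None = None
    seed: int | None = None
    diverged: bool = False

    @property
    def n_parcels(self) -> int:
        return self.states.shape[0]

    @property
    def n_steps(self) -> int:
        return self.states.shape[1]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[:, -1]


@dataclass
class NoiseSpec:
    """Process-noise scale per parcel and observation signal-to-noise ratio."""

    process_sd: np.ndarray | float = 0.0
    obs_snr: float = 50.0

    def sd_vector(self, n: int) -> np.ndarray:
        sd = np.asarray(self.process_sd, dtype=np.float64)
        if sd.ndim == 0:
            sd = np.full(n, float(sd))
        if sd.shape != (n,) or np.any(sd < 0):
            raise ValueError("process_sd must be a nonnegative scalar or (n,) vector")
        return sd


def _iterate(params: MindyXParams, x0: np.ndarray, U: np.ndarray | None,
             steps: int, noise_sd: np.ndarray | None,
             rng: np.random.Generator | None) -> tuple[np.ndarray, bool]:
    """Shared iteration core. ``x0`` may be (n,) or (n, n_traj) for
    vectorized multi-start simulation; ``U`` is (m, steps) or None."""
    W = assemble_connectivity(params)
    x = np.asarray(x0, dtype=np.float64)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    out = np.empty((x.shape[0], x.shape[1], steps))
    diverged = False
    for t in range(steps):
        u = U[:, t] if U is not None else None
        xb = step(params, x, None, W=W)
        if u is not None:
            xb = xb + (params.B @ u)[:, None]
        if noise_sd is not None and rng is not None:
            xb = xb + noise_sd[:, None] * rng.standard_normal(x.shape)
        x = xb
        if np.max(np.abs(x)) > DIVERGENCE_BOUND:
            diverged = True
            out[:, :, t:] = x[:, :, None]
            break
        out[:, :, t] = x
    return (out[:, 0, :], diverged) if squeeze else (out, diverged)


def simulate_noise_free(params: MindyXParams, u_const: np.ndarray | None,
                        x0: np.ndarray, steps: int) -> Trajectory:
    """Deterministically iterate the model under a constant input.

    Used for attractor identification; trajectories whose sup-norm exceeds
    ``DIVERGENCE_BOUND`` are returned with ``diverged=True``.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    U = None
    if u_const is not None:
        u_const = np.asarray(u_const, dtype=np.float64)
        U = np.tile(u_const[:, None], (1, steps))
    states, div = _iterate(params, x0, U, steps, None, None)
    return Trajectory(states=states, input=u_const, diverged=div)


def simulate_noise_free_multi(params: MindyXParams, u_const: np.ndarray | None,
                              X0: np.ndarray, steps: int) -> tuple[np.ndarray, bool]:
    """Vectorized noise-free simulation from many initial conditions.

    ``X0`` is (n, n_traj); returns (states (n, n_traj, steps), any_diverged).
    """
    U = None
    if u_const is not None:
        u_const = np.asarray(u_const, dtype=np.float64)
        U = np.tile(u_const[:, None], (1, steps))
    return _iterate(params, X0, U, steps, None, None)


def simulate_noise_driven(params: MindyXParams, design: TaskDesign,
                          noise: NoiseSpec, warmup: int = 1000,
                          rng: np.random.Generator | None = None,
                          x0: np.ndarray | None = None) -> Trajectory:
    """Noise-driven simulation under a full task design.

    The model first runs freely (zero input, with process noise) for
    ``warmup`` steps to settle onto its noisy steady state; those steps are
    discarded. It is then driven by the design's input sequence, with
    independent Gaussian process noise injected into each parcel at every
    step.
    """
    rng = rng if rng is not None else np.random.default_rng()
    sd = noise.sd_vector(params.n)
    if x0 is None:
        x0 = rng.standard_normal(params.n)
    if warmup > 0:
        warm, div = _iterate(params, x0, None, warmup, sd, rng)
        x0 = warm[:, -1]
        if div:
            return Trajectory(states=warm, input=design.u, diverged=True)
    states, div = _iterate(params, x0, design.u, design.n_volumes, sd, rng)
    return Trajectory(states=states, input=design.u, diverged=div)


def generate_bold(traj: Trajectory, hrf: HRFKernel, noise: NoiseSpec,
                  rng: np.random.Generator | None = None,
                  condition: np.ndarray | None = None,
                  run_id: str = "", modality: str = "rest") -> BoldRun:
    """Observation model: causal HRF convolution plus observation noise.

    Each parcel's trajectory is convolved with the kernel (output truncated
    to the trajectory length) and Gaussian noise with variance equal to that
    parcel's neural-signal variance divided by ``noise.obs_snr`` is added
    (the SNR convention references the underlying signal x, matching the
    prior the Wiener deconvolution assumes).
    """
    if traj.n_steps < hrf.h.size:
        raise ValueError("trajectory shorter than the HRF support")
    y = np.apply_along_axis(
        lambda s: np.convolve(s, hrf.h)[: traj.n_steps], 1, traj.states
    )
    if noise.obs_snr is not None and np.isfinite(noise.obs_snr):
        if noise.obs_snr <= 0:
            raise ValueError("obs_snr must be positive")
        if rng is None:
            rng = np.random.default_rng()
        sd = traj.states.std(axis=1, keepdims=True) / np.sqrt(noise.obs_snr)
        y = y + sd * rng.standard_normal(y.shape)
    return BoldRun(data=y, tr=hrf.tr, condition=condition, run_id=run_id,
                   modality=modality, kind="bold")
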