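"""Ground-truth models and full synthetic rest + task sessions.

The generator emulates, at desk scale, the layout of a joint resting-state /
N-back session: several resting runs, plus block-design task runs with two
alternating conditions separated by intervals, sampled at the scanner TR.
Neural states evolve by the network model with Gaussian process noise; BOLD
is produced by HRF convolution plus observation noise at a 50:1
signal-to-noise ratio. Ground-truth connectivity is constructed per dynamical
regime (monostable / multistable / oscillatory) and verified post hoc with
the attractor-identification machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attractors import find_attractors
from .model import MindyXParams, activation_slope_at_zero
from .preprocess import BoldRun, TaskDesign, build_design, canonical_hrf
from .simulate import NoiseSpec, generate_bold, simulate_noise_driven

__all__ = ["SynthConfig", "make_ground_truth", "synthesize_session",
           "task_labels"]


@dataclass
class SynthConfig:
    """Study-layout and generative settings for one synthetic session.

    Defaults are a scaled mirror of a rest + N-back protocol: 15 parcels,
    rank-5 low-rank connectivity, two ~12-minute resting runs, one task run
    with four 25 s blocks per condition, TR 0.72 s, observation SNR 50:1.
    """

    n_parcels: int = 15
    rank_k: int = 5
    regime: str = "multistable"
    n_rest_runs: int = 2
    rest_T: int = 1000
    n_task_runs: int = 1
    task_T: int = 400
    block_length_s: float = 25.0
    n_blocks_per_condition: int = 4
    tr: float = 0.72
    process_sd: float = 0.3
    obs_snr: float = 50.0
    conditions: tuple[str, ...] = ("cond_1", "cond_2")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_parcels, self.rank_k, self.rest_T, self.task_T) < 1:
            raise ValueError("counts must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.regime not in {"monostable", "multistable", "oscillatory", "mixed"}:
            raise ValueError(f"unknown regime {self.regime!r}")


def task_labels(cfg: SynthConfig) -> np.ndarray:
    """Per-volume labels of one block-design task run.

    Blocks of the two conditions alternate, separated by equal intervals;
    any remainder volumes extend the final interval.
    """
    block_vols = max(1, int(round(cfg.block_length_s / cfg.tr)))
    n_blocks = 2 * cfg.n_blocks_per_condition
    gap_total = cfg.task_T - n_blocks * block_vols
    if gap_total < n_blocks + 1:
        raise ValueError("task_T too short for the requested block layout")
    gap = gap_total // (n_blocks + 1)
    labels = np.full(cfg.task_T, "interval", dtype=object)
    pos = gap
    for i in range(n_blocks):
        cond = cfg.conditions[i % 2]
        labels[pos:pos + block_vols] = cond
        pos += block_vols + gap
    return labels


def _sparse_noise(rng, n: int, density: float, scale: float) -> np.ndarray:
    """Sparse random matrix: each entry nonzero with prob ``density``."""
    mask = rng.random((n, n)) < density
    return mask * rng.normal(0.0, scale, (n, n))


def _base_params(cfg: SynthConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    D = rng.uniform(0.2, 0.8, cfg.n_parcels)
    alpha = rng.uniform(4.0, 6.0, cfg.n_parcels)
    return D, alpha


def _planted_vector(rng, n: int) -> np.ndarray:
    """A unit-norm +/- pattern splitting the parcels into two groups."""
    v = rng.choice([-1.0, 1.0], size=n)
    return v / np.linalg.norm(v)


def _build_candidate(cfg: SynthConfig, rng, gain: float) -> MindyXParams:
    n, k = cfg.n_parcels, cfg.rank_k
    D, alpha = _base_params(cfg, rng)
    g0 = float(activation_slope_at_zero(alpha).mean())
    d_bar = float(D.mean())
    W1 = np.zeros((n, k))
    W2 = np.zeros((n, k))

    if cfg.regime == "monostable":
        # Keep the linearization (and, via saturation, the global map)
        # contractive: no planted structure, weak sparse background only.
        ws_scale = 0.4 * D.min() / (g0 * np.sqrt(n))
        Ws = _sparse_noise(rng, n, density=0.3, scale=ws_scale)
        W1[:, 0] = rng.normal(0, ws_scale, n)
        W2[:, 0] = rng.normal(0, ws_scale, n)
    elif cfg.regime == "multistable":
        # Plant a symmetric recurrent loop along a +/- pattern v: the origin
        # destabilizes along v (gain * slope > decay) and saturation creates
        # a stable root on each side.
        v = _planted_vector(rng, n)
        w_eff = gain * d_bar / g0
        W1[:, 0] = w_eff * v
        W2[:, 0] = v
        ws_scale = 0.1 * D.min() / (g0 * np.sqrt(n))
        Ws = _sparse_noise(rng, n, density=0.3, scale=ws_scale)
    else:  # oscillatory
        # Plant a rotational (skew-symmetric) two-dimensional loop with
        # supercritical gain: the origin spirals out, saturation bounds the
        # orbit, yielding a stable invariant circle.
        v1 = _planted_vector(rng, n)
        u2 = _planted_vector(rng, n)
        v2 = u2 - (u2 @ v1) * v1
        v2 /= np.linalg.norm(v2)
        theta = np.pi / 10
        rho = gain * d_bar / g0
        W1[:, 0] = rho * (np.cos(theta) * v1 + np.sin(theta) * v2)
        W2[:, 0] = v1
        W1[:, 1] = rho * (np.cos(theta) * v2 - np.sin(theta) * v1)
        W2[:, 1] = v2
        ws_scale = 0.1 * D.min() / (g0 * np.sqrt(n))
        Ws = _sparse_noise(rng, n, density=0.3, scale=ws_scale)

    # Task-input weights with a planted task-positive / task-negative split.
    half = cfg.n_parcels // 2
    sign = np.ones(cfg.n_parcels)
    sign[half:] = -1.0
    sign = sign[rng.permutation(cfg.n_parcels)]
    mag = rng.uniform(0.05, 0.15, (cfg.n_parcels, len(cfg.conditions)))
    B = sign[:, None] * mag
    B[:, -1] *= 1.5  # the demanding condition drives harder
    return MindyXParams(Ws=Ws, W1=W1, W2=W2, alpha=alpha, D=D, B=B, tr=cfg.tr)


_EXPECTED = {
    "monostable": lambda a: a.topology == "monostable",
    "multistable": lambda a: a.topology == "multistable",
    "oscillatory": lambda a: a.topology == "oscillatory",
}


def make_ground_truth(cfg: SynthConfig,
                      rng: np.random.Generator | None = None,
                      max_tries: int = 8) -> MindyXParams:
    """Construct a ground-truth model of the requested dynamical regime.

    The construction targets the regime through the linearized gain around
    the origin; because the nonlinear landscape is not fully analytic for
    n > 2, each candidate is verified with the attractor search (under zero
    input) and the gain along the planted structure is adjusted over a
    bounded number of retries. Deterministic given the generator state.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    regime = cfg.regime
    if regime == "mixed":
        regime = rng.choice(["monostable", "multistable", "oscillatory"])
        cfg = SynthConfig(**{**cfg.__dict__, "regime": str(regime)})
    gain = 1.0 if regime == "monostable" else 1.6
    for _ in range(max_tries):
        params = _build_candidate(cfg, rng, gain)
        attrs = find_attractors(params, u_const=None, n_init=40, steps=1600,
                                rng=np.random.default_rng(rng.integers(2**31)))
        if not attrs.unclassified_flag and attrs.topology and \
                _EXPECTED[regime](attrs):
            return params
        gain *= 1.15  # strengthen the planted loop and retry
    raise RuntimeError(f"could not realize a {regime!r} ground-truth model "
                       f"in {max_tries} attempts")


def synthesize_session(params: MindyXParams, cfg: SynthConfig,
                       rng: np.random.Generator | None = None):
    """Generate a full session from a ground-truth model.

    Returns ``(bold_runs, designs, neural_runs)``: resting runs (zero input)
    and block-design task runs, with the ground-truth neural trajectories
    alongside the noisy BOLD observations. All randomness derives from
    ``rng`` (or ``cfg.seed``).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    hrf = canonical_hrf(cfg.tr)
    noise = NoiseSpec(process_sd=cfg.process_sd, obs_snr=cfg.obs_snr)
    bold_runs, designs, neural_runs = [], [], []

    def _one_run(labels, run_id, modality):
        design = build_design(labels, cfg.conditions)
        traj = simulate_noise_driven(params, design, noise, warmup=1000, rng=rng)
        if traj.diverged:
            raise FloatingPointError(f"simulation diverged in run {run_id}")
        bold = generate_bold(traj, hrf, noise, rng=rng, condition=labels,
                             run_id=run_id, modality=modality)
        neural = BoldRun(data=traj.states, tr=cfg.tr, condition=labels,
                         run_id=run_id, modality=modality, kind="neural")
        bold_runs.append(bold)
        designs.append(design)
        neural_runs.append(neural)

    for r in range(cfg.n_rest_runs):
        labels = np.full(cfg.rest_T, "rest", dtype=object)
        _one_run(labels, f"rest_{r+1}", "rest")
    for r in range(cfg.n_task_runs):
        _one_run(task_labels(cfg), f"task_{r+1}", "task")
    return bold_runs, designs, neural_runs
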