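"""Shared fixtures: tiny analytic systems and one synthetic session.

The 1-D and 2-D constructions have attractors that an independent dense
root-finding / winding-number oracle can enumerate, so the attractor search
can be checked against ground truth. The session bundle is generated once
per test session at the default desk-scale study conditions.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq

import mindyx as mx


def make_1d_model(w: float = 0.3, d: float = 0.5, alpha: float = 2.0,
                  b_in: float = 0.5) -> mx.MindyXParams:
    """Scalar model x' = x + w psi(x) - d x + b_in u.

    With w * psi'(0) > d the origin is unstable and saturation creates a
    stable root on each side (a bistable landscape); a large enough input
    tilts it to a single root.
    """
    return mx.MindyXParams(
        Ws=np.array([[w]]), W1=np.zeros((1, 1)), W2=np.zeros((1, 1)),
        alpha=np.array([alpha]), D=np.array([d]), B=np.array([[b_in]]),
    )


def stable_roots_1d(params: mx.MindyXParams, u: float = 0.0,
                    lo: float = -5.0, hi: float = 5.0, n_grid: int = 20001):
    """Independent oracle: all fixed points of the scalar map by dense
    sign-scan + bisection, split into stable and unstable by the map slope.

    Fixed points solve w psi(x) - d x + b u = 0; a root is stable iff
    |1 + w psi'(x) - d| < 1.
    """
    w = float(params.Ws[0, 0])
    d = float(params.D[0])
    a = params.alpha
    drive = float(params.B[0, 0]) * u

    def g(x):
        return w * float(mx.activation(np.array([x]), a)[0]) - d * x + drive

    xs = np.linspace(lo, hi, n_grid)
    gs = np.array([g(x) for x in xs])
    roots = []
    for i in np.flatnonzero(np.sign(gs[:-1]) * np.sign(gs[1:]) < 0):
        roots.append(brentq(g, xs[i], xs[i + 1], xtol=1e-12))
    roots.extend(xs[np.flatnonzero(gs == 0)])
    stable, unstable = [], []
    for r in sorted(roots):
        slope = 1 + w * float(mx.activation_deriv(np.array([r]), a)[0]) - d
        (stable if abs(slope) < 1 else unstable).append(r)
    return np.array(stable), np.array(unstable)


def make_2d_rotational(rho: float = 0.6, theta: float = 2 * np.pi / 20,
                       d: float = 0.5, alpha: float = 5.0) -> mx.MindyXParams:
    """Planar model with a rotational coupling and saturating activation.

    The linearization spirals outward from the origin; saturation bounds the
    orbit, leaving a stable invariant loop (a limit cycle of the map).
    """
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    return mx.MindyXParams(
        Ws=rho * R, W1=np.zeros((2, 1)), W2=np.zeros((2, 1)),
        alpha=np.full(2, alpha), D=np.full(2, d), B=np.zeros((2, 1)),
    )


def winding_period_2d(params: mx.MindyXParams, steps: int = 6000,
                      discard: int = 2000) -> float:
    """Independent oracle for the 2-D cycle period: mean angular advance per
    step on the settled orbit, measured by unwrapped polar angle."""
    traj = mx.simulate_noise_free(params, None, np.array([1.0, 0.0]), steps)
    z = traj.states[:, discard:]
    ang = np.unwrap(np.arctan2(z[1], z[0]))
    dtheta = (ang[-1] - ang[0]) / (ang.size - 1)
    return float(2 * np.pi / abs(dtheta))


def random_params(rng: np.random.Generator, n: int = 6, k: int = 2,
                  m: int = 2) -> mx.MindyXParams:
    return mx.MindyXParams(
        Ws=rng.normal(0, 0.2, (n, n)), W1=rng.normal(0, 0.2, (n, k)),
        W2=rng.normal(0, 0.2, (n, k)), alpha=rng.uniform(0.5, 8, n),
        D=rng.uniform(0.1, 0.9, n), B=rng.normal(0, 0.2, (n, m)),
    )


@pytest.fixture(scope="session")
def session_bundle():
    """One multistable ground truth plus a full synthetic session."""
    cfg = mx.SynthConfig(seed=3)
    rng = np.random.default_rng(3)
    gt = mx.make_ground_truth(cfg, rng)
    bold, designs, neural = mx.synthesize_session(gt, cfg, rng)
    return cfg, gt, bold, designs, neural


@pytest.fixture(scope="session")
def fitted_bundle(session_bundle):
    """A model fit on the session's neural runs (shared across tests)."""
    cfg, gt, bold, designs, neural = session_bundle
    params, report = mx.fit_mindyx(
        neural, designs, mx.FitConfig(n_minibatches=2000, seed=11))
    return session_bundle + (params, report)
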