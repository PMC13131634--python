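"""Core neural-mass network model: parameters, activation, dynamics, loss.

The model describes parcellated brain activity as a discrete-time nonlinear
dynamical system over ``n`` interconnected neural masses,

    x_{t+1} = x_t + W psi_a(x_t) - D * x_t + B u_t  (+ process noise),

where ``W = Ws + W1 @ W2.T`` is an effective-connectivity matrix with a
sparse-plus-low-rank structure, ``D`` is a per-parcel decay (local
inhibition) rate, ``B`` couples exogenous task regressors ``u_t`` to parcel
excitability, and ``psi_a`` is a parameterized sigmoid whose per-parcel
curvature ``alpha`` interpolates between step-like and near-linear transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "B_SCALE",
    "MindyXParams",
    "LossConfig",
    "activation",
    "activation_deriv",
    "activation_slope_at_zero",
    "assemble_connectivity",
    "step",
    "loss",
]

#: Fixed slope scale of the activation function.
B_SCALE = 20.0 / 3.0


def _as_1d(v, n: int, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    if v.ndim == 0:
        v = np.full(n, float(v))
    if v.shape != (n,):
        raise ValueError(f"{name} must have shape ({n},), got {v.shape}")
    return v


@dataclass
class MindyXParams:
    """All parameters of the network model.

    Attributes
    ----------
    Ws : (n, n) sparse component of the effective connectivity.
    W1, W2 : (n, k) low-rank factors; the low-rank component is ``W1 @ W2.T``.
    alpha : (n,) nonnegative activation curvature per parcel.
    D : (n,) nonnegative decay rate per parcel.
    B : (n, m) task-input weights, one column per task regressor.
    b : fixed activation slope scale (20/3).
    """

    Ws: np.ndarray
    W1: np.ndarray
    W2: np.ndarray
    alpha: np.ndarray
    D: np.ndarray
    B: np.ndarray
    b: float = B_SCALE
    tr: float | None = None

    def __post_init__(self) -> None:
        self.Ws = np.asarray(self.Ws, dtype=np.float64)
        if self.Ws.ndim != 2 or self.Ws.shape[0] != self.Ws.shape[1]:
            raise ValueError(f"Ws must be square, got {self.Ws.shape}")
        n = self.Ws.shape[0]
        self.W1 = np.asarray(self.W1, dtype=np.float64)
        self.W2 = np.asarray(self.W2, dtype=np.float64)
        if self.W1.ndim != 2 or self.W1.shape[0] != n:
            raise ValueError(f"W1 must be (n, k) with n={n}, got {self.W1.shape}")
        if self.W2.shape != self.W1.shape:
            raise ValueError(
                f"W1/W2 shape mismatch: {self.W1.shape} vs {self.W2.shape}"
            )
        self.alpha = _as_1d(self.alpha, n, "alpha")
        self.D = _as_1d(self.D, n, "D")
        if np.any(self.alpha < 0):
            raise ValueError("alpha must be nonnegative")
        if np.any(self.D < 0):
            raise ValueError("D must be nonnegative")
        self.B = np.asarray(self.B, dtype=np.float64)
        if self.B.ndim == 1:
            self.B = self.B[:, None]
        if self.B.shape[0] != n:
            raise ValueError(f"B must have n={n} rows, got {self.B.shape}")

    @property
    def n(self) -> int:
        """Number of parcels (state dimension)."""
        return self.Ws.shape[0]

    @property
    def k(self) -> int:
        """Rank bound of the low-rank connectivity component."""
        return self.W1.shape[1]

    @property
    def m(self) -> int:
        """Number of task regressors (columns of B)."""
        return self.B.shape[1]

    @property
    def W(self) -> np.ndarray:
        """Effective connectivity ``Ws + W1 @ W2.T``."""
        return assemble_connectivity(self)

    def copy(self) -> "MindyXParams":
        return replace(
            self,
            Ws=self.Ws.copy(),
            W1=self.W1.copy(),
            W2=self.W2.copy(),
            alpha=self.alpha.copy(),
            D=self.D.copy(),
            B=self.B.copy(),
        )


@dataclass
class LossConfig:
    """Regularization weights of the training loss.

    lambda1 penalizes |Ws| entrywise, lambda2 adds an extra penalty on the
    diagonal of Ws (suppressing redundancy with the decay term), lambda3
    penalizes |W1| and |W2|.
    """

    lambda1: float = 0.075
    lambda2: float = 0.2
    lambda3: float = 0.05

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("regularization weights must be nonnegative")


def activation(x, alpha, b: float = B_SCALE) -> np.ndarray:
    """Parameterized sigmoid psi_a(x), elementwise, with range (-1, 1).

    psi_a(x) = sqrt(a^2 + (b x + 1/2)^2) - sqrt(a^2 + (b x - 1/2)^2).

    ``alpha`` broadcasts against ``x`` along the first (parcel) axis; small
    alpha gives a step-like response, large alpha a flat, near-linear one.
    """
    x = np.asarray(x, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    if np.any(alpha < 0):
        raise ValueError("alpha must be nonnegative")
    if x.ndim == 2 and alpha.ndim == 1:
        alpha = alpha[:, None]
    a2 = alpha**2
    return np.sqrt(a2 + (b * x + 0.5) ** 2) - np.sqrt(a2 + (b * x - 0.5) ** 2)


def activation_deriv(x, alpha, b: float = B_SCALE) -> np.ndarray:
    """Elementwise derivative of the activation with respect to x."""
    x = np.asarray(x, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    if x.ndim == 2 and alpha.ndim == 1:
        alpha = alpha[:, None]
    a2 = alpha**2
    p = b * x + 0.5
    q = b * x - 0.5
    return b * (p / np.sqrt(a2 + p**2) - q / np.sqrt(a2 + q**2))


def activation_slope_at_zero(alpha, b: float = B_SCALE) -> np.ndarray:
    """Slope of the activation at the origin: b / sqrt(alpha^2 + 1/4)."""
    alpha = np.asarray(alpha, dtype=np.float64)
    if np.any(alpha < 0):
        raise ValueError("alpha must be nonnegative")
    return b / np.sqrt(alpha**2 + 0.25)


def assemble_connectivity(params: MindyXParams) -> np.ndarray:
    """Effective connectivity W = Ws + W1 @ W2.T."""
    return params.Ws + params.W1 @ params.W2.T


def step(params: MindyXParams, x: np.ndarray, u: np.ndarray | None = None,
         W: np.ndarray | None = None) -> np.ndarray:
    """One noise-free step of the dynamics.

    ``x`` may be a single state ``(n,)`` or a batch ``(n, S)``; ``u``
    broadcasts likewise. ``W`` may be passed to avoid re-assembling the
    connectivity inside tight loops.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("state contains non-finite entries")
    if W is None:
        W = assemble_connectivity(params)
    psi = activation(x, params.alpha, params.b)
    decay = params.D[:, None] * x if x.ndim == 2 else params.D * x
    out = x + W @ psi - decay
    if u is not None:
        u = np.asarray(u, dtype=np.float64)
        out = out + params.B @ u
    return out


def loss(params: MindyXParams, X: np.ndarray, U: np.ndarray | None,
         Xnext: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Training loss on a batch of one-step transitions.

    Mean over triplets of the half squared one-step prediction error plus the
    l1 penalties (added once per batch): lambda1 |Ws| + lambda2 |diag Ws|
    + lambda3 (|W1| + |W2|).
    """
    cfg = cfg or LossConfig()
    X = np.asarray(X, dtype=np.float64)
    Xnext = np.asarray(Xnext, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
        Xnext = Xnext[:, None]
        if U is not None:
            U = np.asarray(U, dtype=np.float64)[:, None]
    if X.size == 0:
        raise ValueError("empty batch")
    pred = step(params, X, U)
    resid = Xnext - pred
    mse_half = 0.5 * np.mean(np.sum(resid**2, axis=0))
    pen = (
        cfg.lambda1 * np.abs(params.Ws).sum()
        + cfg.lambda2 * np.abs(np.diag(params.Ws)).sum()
        + cfg.lambda3 * (np.abs(params.W1).sum() + np.abs(params.W2).sum())
    )
    return float(mse_half + pen)
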