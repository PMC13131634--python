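"""Parameter estimation from deconvolved runs.

The network model is fit by minibatch NADAM on the regularized one-step
prediction loss, with the l1 penalties applied by proximal soft-thresholding
(so the sparse component contains exact zeros), followed by a global
least-squares rescaling of W, D and B that compensates for regularization
shrinkage. Linear baselines (VARX(1,1), ARX(1,1), GLM) and cross-validated
one-step R-squared are provided for model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .model import (
    LossConfig,
    MindyXParams,
    activation,
    assemble_connectivity,
)
from .preprocess import BoldRun, TaskDesign

__all__ = [
    "FitConfig",
    "RescaleFactors",
    "FitReport",
    "BaselineParams",
    "stack_triplets",
    "sample_minibatch",
    "fit_mindyx",
    "global_rescale",
    "crossval_r2",
    "fit_baseline",
    "one_step_predict",
    "prediction_noise_sd",
]

VARX_LAMBDA_GRID = (0.0, 0.001, 0.005, 0.01, 0.05)


@dataclass
class FitConfig:
    """Everything that controls a model fit; fully determines the result
    together with the data and the seed."""

    loss_cfg: LossConfig = field(default_factory=LossConfig)
    rank_k: int | None = None          # default min(72, n - 1)
    batch_size: int = 300
    n_minibatches: int = 5000
    learning_rate: float = 2e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    init_scale: float = 0.01
    init_alpha: float = 5.0
    init_decay: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.n_minibatches < 1:
            raise ValueError("batch_size and n_minibatches must be >= 1")


@dataclass
class RescaleFactors:
    """Scalar rescaling factors for the connectivity, decay and input terms,
    with flags for terms that were degenerate in the training data."""

    pW: float = 1.0
    pD: float = 1.0
    pB: float = 1.0
    degenerate: tuple = ()


@dataclass
class FitReport:
    loss_trace: np.ndarray = None        # composite (penalized) minibatch loss
    mse_trace: np.ndarray = None         # half mean squared misfit component
    r2_train: float = np.nan
    r2_train_parcel: np.ndarray = None
    r2_val: float = np.nan
    r2_val_parcel: np.ndarray = None
    rescale: RescaleFactors = None
    noise_sd: np.ndarray = None
    seed: int = 0


def _design_matrix(run: BoldRun, design: TaskDesign | None, m: int) -> np.ndarray:
    if design is None:
        return np.zeros((m, run.n_volumes))
    if design.n_volumes != run.n_volumes:
        raise ValueError("design length must match the run")
    return design.u


def _infer_m(designs) -> int:
    for d in designs:
        if d is not None:
            return d.m
    return 2


def stack_triplets(runs, designs=None):
    """Stack all one-step transitions (x_t, u_t, x_{t+1}) across runs.

    Consecutive volumes are paired within runs only, never across run
    boundaries. Returns (X, U, Xnext) with samples as columns.
    """
    if designs is None:
        designs = [None] * len(runs)
    m = _infer_m(designs)
    Xs, Us, Xn = [], [], []
    for run, des in zip(runs, designs):
        u = _design_matrix(run, des, m)
        Xs.append(run.data[:, :-1])
        Us.append(u[:, :-1])
        Xn.append(run.data[:, 1:])
    return np.hstack(Xs), np.hstack(Us), np.hstack(Xn)


def sample_minibatch(runs, designs, size: int, rng: np.random.Generator):
    """Uniformly sample one-step triplets across all runs.

    Equivalent to drawing (run, t) pairs uniformly over all valid
    consecutive-volume pairs; t and t+1 always lie within one run.
    """
    X, U, Xn = stack_triplets(runs, designs)
    if X.shape[1] == 0:
        raise ValueError("no valid consecutive-volume pairs")
    idx = rng.integers(0, X.shape[1], size=size)
    return X[:, idx], U[:, idx], Xn[:, idx]


def _soft_threshold(A: np.ndarray, t) -> np.ndarray:
    return np.sign(A) * np.maximum(np.abs(A) - t, 0.0)


def _gradients(params: MindyXParams, X, U, Xn, W):
    """Analytic gradients of the (unpenalized) mean half-SSE over the batch."""
    S = X.shape[1]
    a = params.alpha[:, None]
    p = params.b * X + 0.5
    q = params.b * X - 0.5
    sp = np.sqrt(a**2 + p**2)
    sq = np.sqrt(a**2 + q**2)
    psi = sp - sq
    pred = X + W @ psi - params.D[:, None] * X + params.B @ U
    R = pred - Xn
    gW = (R @ psi.T) / S
    gD = -np.mean(R * X, axis=1)
    gB = (R @ U.T) / S
    dpsi_da = a * (1.0 / sp - 1.0 / sq)
    gAlpha = np.mean((W.T @ R) * dpsi_da, axis=1)
    half_mse = 0.5 * np.mean(np.sum(R**2, axis=0))
    return gW, gD, gB, gAlpha, half_mse


def fit_mindyx(runs, designs=None, cfg: FitConfig | None = None, tr: float | None = None):
    """Fit the nonlinear network model by minibatch NADAM.

    Parameters are initialized small (alpha at its typical fitted value of
    ~5, decay at 0.5) and updated from 300-triplet minibatches; the l1
    penalties on Ws, W1, W2 (plus the extra diagonal penalty on Ws) are
    applied as proximal soft-thresholding after each step, and alpha and D
    are projected to stay positive. The last 10% of each run is held out as
    an internal validation segment used to estimate the per-parcel
    prediction-noise scale and a validation R-squared; training triplets are
    drawn only from the first 90%. A final global rescaling compensates for
    the shrinkage bias of the penalties.

    Returns ``(params, report)``; the whole procedure is deterministic given
    ``cfg.seed``.
    """
    cfg = cfg or FitConfig()
    if designs is None:
        designs = [None] * len(runs)
    rng = np.random.default_rng(cfg.seed)
    n = runs[0].n_parcels
    m = _infer_m(designs)
    k = cfg.rank_k if cfg.rank_k is not None else min(72, max(1, n - 1))
    tr = tr if tr is not None else runs[0].tr

    # Internal split: last 10% of each run for validation / noise calibration.
    train_runs, val_runs, train_des, val_des = [], [], [], []
    for run, des in zip(runs, designs):
        T = run.n_volumes
        cut = max(2, int(round(T * 0.9)))
        u = _design_matrix(run, des, m)
        train_runs.append(run.slice_volumes(0, cut))
        train_des.append(TaskDesign(u[:, :cut], des.conditions if des is not None
                                    else tuple(f"cond_{j+1}" for j in range(m))))
        if T - cut >= 2:
            val_runs.append(run.slice_volumes(cut, T))
            val_des.append(TaskDesign(u[:, cut:], train_des[-1].conditions))

    X_all, U_all, Xn_all = stack_triplets(train_runs, train_des)
    S_all = X_all.shape[1]
    if S_all == 0:
        raise ValueError("no training triplets")

    sc = cfg.init_scale
    params = MindyXParams(
        Ws=rng.normal(0.0, sc, (n, n)),
        W1=rng.normal(0.0, sc, (n, k)),
        W2=rng.normal(0.0, sc, (n, k)),
        alpha=np.full(n, cfg.init_alpha),
        D=np.full(n, cfg.init_decay),
        B=rng.normal(0.0, sc, (n, m)),
        tr=tr,
    )
    lam = cfg.loss_cfg
    lr, b1, b2, eps = cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.epsilon
    names = ["Ws", "W1", "W2", "alpha", "D", "B"]
    mom = {nm: np.zeros_like(getattr(params, nm)) for nm in names}
    vel = {nm: np.zeros_like(getattr(params, nm)) for nm in names}
    trace = np.empty(cfg.n_minibatches)
    mse_trace = np.empty(cfg.n_minibatches)

    for it in range(1, cfg.n_minibatches + 1):
        idx = rng.integers(0, S_all, size=cfg.batch_size)
        X, U, Xn = X_all[:, idx], U_all[:, idx], Xn_all[:, idx]
        W = assemble_connectivity(params)
        gW, gD, gB, gAlpha, half_mse = _gradients(params, X, U, Xn, W)
        grads = {
            "Ws": gW,
            "W1": gW @ params.W2,
            "W2": gW.T @ params.W1,
            "alpha": gAlpha,
            "D": gD,
            "B": gB,
        }
        pen = (lam.lambda1 * np.abs(params.Ws).sum()
               + lam.lambda2 * np.abs(np.diag(params.Ws)).sum()
               + lam.lambda3 * (np.abs(params.W1).sum() + np.abs(params.W2).sum()))
        trace[it - 1] = half_mse + pen
        mse_trace[it - 1] = half_mse
        if not np.isfinite(trace[it - 1]):
            raise FloatingPointError(
                f"non-finite loss at minibatch {it}; try a smaller learning rate")
        # NADAM (Nesterov-accelerated Adam) update with a linearly decaying
        # learning rate (removes the oscillation floor late in training).
        lr_t = lr * (1.0 - 0.9 * (it - 1) / cfg.n_minibatches)
        for nm in names:
            g = grads[nm]
            mom[nm] = b1 * mom[nm] + (1 - b1) * g
            vel[nm] = b2 * vel[nm] + (1 - b2) * g**2
            m_hat = mom[nm] / (1 - b1 ** (it + 1)) + (1 - b1) * g / (1 - b1**it)
            v_hat = vel[nm] / (1 - b2**it)
            setattr(params, nm,
                    getattr(params, nm) - lr_t * m_hat / (np.sqrt(v_hat) + eps))
        # Proximal l1 on the sparse/low-rank factors; positivity projection
        # on the curvature and decay.
        thr = lr_t * lam.lambda1 * np.ones((n, n))
        np.fill_diagonal(thr, lr_t * (lam.lambda1 + lam.lambda2))
        params.Ws = _soft_threshold(params.Ws, thr)
        params.W1 = _soft_threshold(params.W1, lr_t * lam.lambda3)
        params.W2 = _soft_threshold(params.W2, lr_t * lam.lambda3)
        params.alpha = np.maximum(params.alpha, 1e-6)
        params.D = np.maximum(params.D, 1e-6)

    params, rescale = global_rescale(params, train_runs, train_des)

    report = FitReport(loss_trace=trace, mse_trace=mse_trace, rescale=rescale,
                       seed=cfg.seed)
    report.r2_train_parcel, report.r2_train = crossval_r2(params, train_runs, train_des)
    if val_runs:
        report.r2_val_parcel, report.r2_val = crossval_r2(params, val_runs, val_des)
        report.noise_sd = prediction_noise_sd(params, val_runs, val_des)
    else:
        report.noise_sd = prediction_noise_sd(params, train_runs, train_des)
    return params, report


def global_rescale(params: MindyXParams, runs, designs=None):
    """Least-squares rescaling of the connectivity, decay and input terms.

    Finds scalars (pW, pD, pB) minimizing the one-step prediction error
    ``||x_{t+1} - (x_t + pW W psi(x_t) - pD D x_t + pB B u_t)||^2`` over all
    training triplets (no intercept) and multiplies them into W (via Ws and
    W1), D and B. A term that is identically zero in the training data (e.g.
    the input term on all-rest data) keeps factor 1 and is flagged.
    """
    X, U, Xn = stack_triplets(runs, designs)
    W = assemble_connectivity(params)
    terms = {
        "W": (W @ activation(X, params.alpha, params.b)).ravel(),
        "D": (-params.D[:, None] * X).ravel(),
        "B": (params.B @ U).ravel(),
    }
    target = (Xn - X).ravel()
    active = [nm for nm, col in terms.items() if np.linalg.norm(col) > 1e-12]
    degenerate = tuple(nm for nm in terms if nm not in active)
    factors = {"W": 1.0, "D": 1.0, "B": 1.0}
    if active:
        A = np.column_stack([terms[nm] for nm in active])
        coef, *_ = np.linalg.lstsq(A, target, rcond=None)
        factors.update(dict(zip(active, coef)))
    out = params.copy()
    out.Ws *= factors["W"]
    out.W1 *= factors["W"]
    out.D = params.D * factors["D"]
    out.B = params.B * factors["B"]
    return out, RescaleFactors(pW=float(factors["W"]), pD=float(factors["D"]),
                               pB=float(factors["B"]), degenerate=degenerate)


@dataclass
class BaselineParams:
    """A fitted linear baseline.

    kind "brainwise_linear" is VARX(1,1) ``x_{t+1} = A x_t + B u_t``;
    kind "decay_only" is ARX(1,1) ``x_{t+1} = D * x_t + B u_t``;
    kind "glm" is the static model ``x_t = mu + beta u_t``.
    """

    kind: str
    A: np.ndarray | None = None
    D: np.ndarray | None = None
    B: np.ndarray | None = None
    mu: np.ndarray | None = None
    beta: np.ndarray | None = None
    lam: float = 0.0


def one_step_predict(model, X: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Predicted next state for a fitted model of any supported kind."""
    if isinstance(model, MindyXParams):
        W = assemble_connectivity(model)
        return (X + W @ activation(X, model.alpha, model.b)
                - model.D[:, None] * X + model.B @ U)
    if model.kind == "brainwise_linear":
        return model.A @ X + model.B @ U
    if model.kind == "decay_only":
        return model.D[:, None] * X + model.B @ U
    raise ValueError(f"{model.kind!r} is not a one-step dynamical model")


def crossval_r2(model, runs, designs=None):
    """One-step coefficient of determination on held-out runs.

    R^2 = 1 - SSE/SST of the actual vs predicted next state, per parcel and
    pooled over parcels. Returns ``(r2_per_parcel, r2_pooled)``.
    """
    X, U, Xn = stack_triplets(runs, designs)
    pred = one_step_predict(model, X, U)
    sst = np.sum((Xn - Xn.mean(axis=1, keepdims=True)) ** 2, axis=1)
    if np.any(sst < 1e-30):
        raise ValueError("constant target series: R^2 undefined")
    sse = np.sum((Xn - pred) ** 2, axis=1)
    return 1.0 - sse / sst, float(1.0 - sse.sum() / sst.sum())


def prediction_noise_sd(params, runs, designs=None) -> np.ndarray:
    """Per-parcel root-mean-squared one-step prediction error.

    Used as the process-noise scale for noise-driven simulation: the
    unexplained one-step variability is attributed to intrinsic noise.
    """
    X, U, Xn = stack_triplets(runs, designs)
    R = Xn - one_step_predict(params, X, U)
    return np.sqrt(np.mean(R**2, axis=1))


def _fit_varx(X, U, Xn, lam: float):
    n, m = X.shape[0], U.shape[0]
    Z = np.vstack([X, U]).T  # samples x (n + m)
    A = np.empty((n, n))
    B = np.empty((n, m))
    pen = np.concatenate([np.full(n, lam), np.zeros(m)])
    for i in range(n):
        if lam == 0.0:
            coef, *_ = np.linalg.lstsq(Z, Xn[i], rcond=None)
        else:
            coef = sm.OLS(Xn[i], Z).fit_regularized(
                method="elastic_net", alpha=pen, L1_wt=1.0).params
        A[i] = coef[:n]
        B[i] = coef[n:]
    return A, B


def fit_baseline(kind: str, runs, designs=None, lambda_grid=VARX_LAMBDA_GRID):
    """Fit one of the linear baseline models.

    The VARX connectivity matrix carries an l1 penalty; the penalty weight is
    chosen from ``lambda_grid`` by one-step R^2 on an internal validation
    split (the last 10% of each run), then the model is refit on all data.
    ARX and GLM are ordinary least squares per parcel.
    """
    if designs is None:
        designs = [None] * len(runs)
    m = _infer_m(designs)
    X, U, Xn = stack_triplets(runs, designs)
    n = X.shape[0]

    if kind == "brainwise_linear":
        grid = tuple(lambda_grid)
        if not grid:
            raise ValueError("empty lambda grid")
        lam_best = grid[0]
        if len(grid) > 1:
            tr_runs, va_runs, tr_des, va_des = [], [], [], []
            for run, des in zip(runs, designs):
                cut = max(2, int(round(run.n_volumes * 0.9)))
                u = _design_matrix(run, des, m)
                conds = tuple(f"cond_{j+1}" for j in range(m))
                tr_runs.append(run.slice_volumes(0, cut))
                tr_des.append(TaskDesign(u[:, :cut], conds))
                if run.n_volumes - cut >= 2:
                    va_runs.append(run.slice_volumes(cut, run.n_volumes))
                    va_des.append(TaskDesign(u[:, cut:], conds))
            if va_runs:
                Xt, Ut, Xnt = stack_triplets(tr_runs, tr_des)
                best = -np.inf
                for lam in grid:
                    A, B = _fit_varx(Xt, Ut, Xnt, lam)
                    cand = BaselineParams(kind=kind, A=A, B=B, lam=lam)
                    _, r2 = crossval_r2(cand, va_runs, va_des)
                    if r2 > best:
                        best, lam_best = r2, lam
        A, B = _fit_varx(X, U, Xn, lam_best)
        return BaselineParams(kind=kind, A=A, B=B, lam=lam_best)

    if kind == "decay_only":
        D = np.empty(n)
        B = np.empty((n, m))
        for i in range(n):
            Z = np.vstack([X[i], U]).T
            coef, *_ = np.linalg.lstsq(Z, Xn[i], rcond=None)
            D[i] = coef[0]
            B[i] = coef[1:]
        return BaselineParams(kind=kind, D=D, B=B)

    if kind == "glm":
        # Static model of the states themselves (not the transitions).
        Xfull = np.hstack([r.data for r in runs])
        Ufull = np.hstack([_design_matrix(r, d, m) for r, d in zip(runs, designs)])
        Z = np.column_stack([np.ones(Xfull.shape[1]), Ufull.T])
        coef, *_ = np.linalg.lstsq(Z, Xfull.T, rcond=None)
        return BaselineParams(kind=kind, mu=coef[0], beta=coef[1:].T)

    raise ValueError(f"unknown baseline kind {kind!r}")
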