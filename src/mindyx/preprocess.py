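"""Time-series preparation for parcellated fMRI runs.

Covers the generic steps between a parcellated BOLD matrix and the "neural"
series the model is fit to: per-parcel detrend/standardization, confound
regression, motion-scrub interpolation, canonical HRF construction, and
Wiener deconvolution under a signal-to-noise prior, plus construction of the
box-car task-design matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal
from scipy.stats import gamma as gamma_dist

__all__ = [
    "BoldRun",
    "HRFKernel",
    "TaskDesign",
    "REST_LABELS",
    "run_stats",
    "normalize_run",
    "regress_confounds",
    "scrub_interpolate",
    "canonical_hrf",
    "wiener_deconvolve",
    "build_design",
    "labels_from_events",
]

#: Condition labels treated as "no task input" (zero input vector).
REST_LABELS = frozenset({"rest", "interval"})


@dataclass
class BoldRun:
    """One scan: a parcel x volume matrix with TR and per-volume labels.

    ``kind`` distinguishes raw/preprocessed BOLD (``"bold"``) from
    deconvolved neural series (``"neural"``); both share this container.
    """

    data: np.ndarray
    tr: float
    condition: np.ndarray | None = None
    run_id: str = ""
    modality: str = "rest"
    kind: str = "bold"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be parcels x volumes (2-D)")
        if self.data.shape[1] < 2:
            raise ValueError("a run needs at least 2 volumes")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.condition is None:
            self.condition = np.full(self.n_volumes, "rest", dtype=object)
        else:
            self.condition = np.asarray(self.condition, dtype=object)
            if self.condition.shape != (self.n_volumes,):
                raise ValueError("condition labels must align with volumes")

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, **kw) -> "BoldRun":
        return replace(self, data=np.asarray(data, dtype=np.float64), **kw)

    def slice_volumes(self, start: int, stop: int) -> "BoldRun":
        return replace(self, data=self.data[:, start:stop],
                       condition=self.condition[start:stop])


# A deconvolved run is a BoldRun with kind="neural"; alias for readability.
NeuralRun = BoldRun


@dataclass
class HRFKernel:
    """Hemodynamic impulse response sampled at the scan TR."""

    h: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        if self.h.ndim != 1 or self.h.size < 2:
            raise ValueError("kernel must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.h)):
            raise ValueError("kernel must be finite")


@dataclass
class TaskDesign:
    """Per-volume exogenous input vectors u_t (m regressors x T volumes)."""

    u: np.ndarray
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 2:
            raise ValueError("u must be m x T")
        self.conditions = tuple(self.conditions)
        if self.u.shape[0] != len(self.conditions):
            raise ValueError("one row of u per condition required")

    @property
    def m(self) -> int:
        return self.u.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.u.shape[1]

    @classmethod
    def rest(cls, n_volumes: int, conditions=("cond_1", "cond_2")) -> "TaskDesign":
        """An all-zero design (resting scan) with the given regressor names."""
        return cls(np.zeros((len(conditions), n_volumes)), conditions)


def run_stats(run: BoldRun, volumes: np.ndarray | None = None):
    """Per-parcel mean and sd, optionally over a subset of volumes.

    For task runs the reference statistics are conventionally taken over the
    block-interval volumes so that interval activity is standardized like
    rest; pass ``volumes = (run.condition == "interval")`` for that.
    """
    data = run.data if volumes is None else run.data[:, np.asarray(volumes)]
    if data.shape[1] < 2:
        raise ValueError("need at least 2 volumes to compute statistics")
    return data.mean(axis=1), data.std(axis=1)


def normalize_run(run: BoldRun, ref_mean: np.ndarray | None = None,
                  ref_sd: np.ndarray | None = None, detrend: bool = True) -> BoldRun:
    """Detrend (linear, per parcel) then standardize by reference statistics.

    With ``ref_mean``/``ref_sd`` omitted the run's own post-detrend statistics
    are used, so each parcel ends with mean 0 and sd 1. Reference statistics
    from another source (e.g. interval volumes, or a same-session resting
    run) may be supplied instead.
    """
    data = run.data
    if detrend:
        data = scipy.signal.detrend(data, axis=1, type="linear")
    if ref_mean is None or ref_sd is None:
        m, s = data.mean(axis=1), data.std(axis=1)
        ref_mean = m if ref_mean is None else np.asarray(ref_mean, float)
        ref_sd = s if ref_sd is None else np.asarray(ref_sd, float)
    else:
        ref_mean = np.asarray(ref_mean, dtype=np.float64)
        ref_sd = np.asarray(ref_sd, dtype=np.float64)
    if np.any(ref_sd < 1e-10):
        raise ValueError("degenerate (near-constant) parcel series: sd ~ 0")
    out = (data - np.asarray(ref_mean)[:, None]) / np.asarray(ref_sd)[:, None]
    return run.with_data(out)


def regress_confounds(run: BoldRun, confounds: np.ndarray) -> BoldRun:
    """Remove confound time courses from every parcel by OLS (with intercept).

    Rank-deficient confound matrices are handled by the pseudo-inverse (a
    warning is emitted).
    """
    C = np.asarray(confounds, dtype=np.float64)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != run.n_volumes:
        raise ValueError("confound rows must align with volumes")
    X = np.column_stack([np.ones(C.shape[0]), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient confounds; using pseudo-inverse",
                      RuntimeWarning, stacklevel=2)
    beta = np.linalg.pinv(X) @ run.data.T
    resid = run.data - (X @ beta).T
    return run.with_data(resid)


def scrub_interpolate(run: BoldRun, fd: np.ndarray, threshold: float):
    """Replace high-motion volumes by linear interpolation.

    Volumes with framewise displacement above ``threshold`` (mm; 0.2 for rest
    and 0.9 for task scans by convention) are replaced by linear
    interpolation between the nearest unflagged neighbors; flagged volumes at
    the run boundary copy the nearest unflagged value.

    Returns ``(scrubbed_run, flagged_fraction)``; the caller may apply the
    usual "more than 1/3 flagged" run-exclusion rule to the fraction.
    """
    fd = np.asarray(fd, dtype=np.float64)
    if fd.shape != (run.n_volumes,):
        raise ValueError("fd must have one value per volume")
    flagged = fd > threshold
    frac = float(flagged.mean())
    if not flagged.any():
        return run.with_data(run.data.copy()), frac
    if flagged.all():
        raise ValueError("all volumes exceed the motion threshold")
    t = np.arange(run.n_volumes)
    good = ~flagged
    out = run.data.copy()
    for i in range(run.n_parcels):
        # np.interp clamps to the boundary values, which implements the
        # nearest-unflagged-copy rule at run edges.
        out[i, flagged] = np.interp(t[flagged], t[good], run.data[i, good])
    return run.with_data(out), frac


def canonical_hrf(tr: float, duration: float = 32.0) -> HRFKernel:
    """Canonical double-gamma HRF sampled at the TR, scaled to unit peak.

    SPM convention: response gamma peaking at 6 s, undershoot gamma peaking
    at 16 s, unit dispersions, undershoot ratio 1/6, 32 s support.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, duration + 1e-9, tr)
    peak = gamma_dist.pdf(t, 6.0, scale=1.0)
    under = gamma_dist.pdf(t, 16.0, scale=1.0)
    h = peak - under / 6.0
    h = h / np.max(np.abs(h))
    return HRFKernel(h=h, tr=tr)


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1)).bit_length()


def wiener_deconvolve(run: BoldRun, hrf: HRFKernel, snr: float = 50.0) -> BoldRun:
    """Estimate the neural series from BOLD by Wiener deconvolution.

    In the frequency domain, ``X(f) = conj(H(f)) Y(f) / (|H(f)|^2 + 1/snr)``,
    the minimum-mean-squared-error inverse filter under a flat signal-to-noise
    ratio of ``snr`` (50:1 by default) across frequency bands. Each parcel is
    mean-removed, zero-padded to the next power of two, filtered, and has its
    mean restored.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if run.n_volumes < hrf.h.size:
        raise ValueError("run shorter than the HRF support")
    T = run.n_volumes
    nfft = _next_pow2(T + hrf.h.size)
    H = np.fft.rfft(hrf.h, nfft)
    gain = np.conj(H) / (np.abs(H) ** 2 + 1.0 / snr)
    # Demean before padding (a nonzero baseline against the zero pad is a
    # step edge that rings); the mean re-enters through the filter's own
    # DC response, exactly as if it had passed through the FFT.
    mean = run.data.mean(axis=1, keepdims=True)
    Y = np.fft.rfft(run.data - mean, nfft, axis=1)
    x = np.fft.irfft(gain * Y, nfft, axis=1)[:, :T] + mean * gain[0].real
    return run.with_data(x, kind="neural")


def build_design(condition: np.ndarray, conditions) -> TaskDesign:
    """Box-car design from per-volume labels: one-hot over task conditions.

    Rest and block-interval volumes map to the zero vector; any label outside
    ``REST_LABELS`` and ``conditions`` is rejected.
    """
    condition = np.asarray(condition, dtype=object)
    conditions = tuple(conditions)
    known = REST_LABELS | set(conditions)
    unknown = {c for c in condition if c not in known}
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    u = np.zeros((len(conditions), condition.size))
    for j, c in enumerate(conditions):
        u[j, condition == c] = 1.0
    return TaskDesign(u=u, conditions=conditions)


def labels_from_events(events, tr: float, n_volumes: int) -> np.ndarray:
    """Per-volume labels from a BIDS-like events table.

    ``events`` needs columns ``onset`` (s), ``duration`` (s), ``trial_type``.
    Volumes not covered by any event are labeled ``"interval"``.
    """
    labels = np.full(n_volumes, "interval", dtype=object)
    t = np.arange(n_volumes) * tr
    for _, row in events.iterrows():
        mask = (t >= float(row["onset"])) & (t < float(row["onset"]) + float(row["duration"]))
        labels[mask] = str(row["trial_type"])
    return labels
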